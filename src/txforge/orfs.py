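"""ORF discovery and completeness classification.

An ORF candidate is classified by which termini it carries: *complete*
(ATG ... stop), *5'-partial* (open at the sequence start, closed by a stop),
*3'-partial* (ATG without a downstream stop), or *internal* (the frame is
open across the whole sequence).  Oriented transcripts are scanned
forward-only; orientation-unknown contigs are scanned in all six frames.
ATG is the only accepted start codon and the standard genetic code is used;
coding potential is judged by length alone (default >= 100 aa, the stop
codon excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParseError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

COMPLETENESS_RANK = {
    "complete": 3,
    "5prime_partial": 2,
    "3prime_partial": 2,
    "internal": 1,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """One maximal ORF on a sequence (coordinates on the scanned strand)."""

    sequence_id: str
    frame: int
    strand: str
    start: int
    end: int
    completeness: str
    aa_length: int


def _scan_frame(
    seq: str, frame: int, sequence_id: str, strand: str, min_aa: int
) -> list[OrfCall]:
    """Report maximal ORFs in one reading frame.

    The frame is cut at stop codons into segments; within each segment the
    first ATG opens the ORF.  A segment with no ATG is only reportable when
    it touches the sequence start (5'-partial) or spans the whole frame with
    no stop at all (internal).
    """
    n = len(seq)
    calls: list[OrfCall] = []
    seg_start = frame  # first base of the current stop-free segment
    first_atg: int | None = None
    any_stop = False
    pos = frame
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon == START_CODON and first_atg is None:
            first_atg = pos
        if codon in STOP_CODONS:
            any_stop = True
            if first_atg is not None:
                aa = (pos - first_atg) // 3
                if aa >= min_aa:
                    calls.append(
                        OrfCall(sequence_id, frame, strand, first_atg, pos + 3,
                                "complete", aa)
                    )
            elif seg_start == frame:
                aa = (pos - seg_start) // 3
                if aa >= min_aa:
                    calls.append(
                        OrfCall(sequence_id, frame, strand, seg_start, pos + 3,
                                "5prime_partial", aa)
                    )
            seg_start = pos + 3
            first_atg = None
        pos += 3
    # trailing open segment
    if first_atg is not None:
        aa = (pos - first_atg) // 3
        if aa >= min_aa:
            calls.append(
                OrfCall(sequence_id, frame, strand, first_atg, pos,
                        "3prime_partial", aa)
            )
    elif not any_stop:
        aa = (pos - frame) // 3
        if aa >= min_aa:
            calls.append(
                OrfCall(sequence_id, frame, strand, frame, pos, "internal", aa)
            )
    return calls


def find_orfs(
    seq: str,
    sequence_id: str = "seq",
    min_aa: int = 100,
    strands: str = "forward",
) -> list[OrfCall]:
    """Find maximal ORFs of at least ``min_aa`` codons (stop excluded).

    ``strands`` is ``"forward"`` for oriented transcripts or ``"both"`` for
    six-frame scanning of orientation-unknown contigs; minus-strand calls
    carry coordinates on the reverse-complemented sequence.
    """
    seq = seq.upper()
    if not seq:
        return []
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParseError(f"sequence {sequence_id}: non-nucleotide characters {sorted(bad)}")
    calls = []
    for frame in range(3):
        calls.extend(_scan_frame(seq, frame, sequence_id, "+", min_aa))
    if strands == "both":
        rc = reverse_complement(seq)
        for frame in range(3):
            calls.extend(_scan_frame(rc, frame, sequence_id, "-", min_aa))
    elif strands != "forward":
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    return calls


def assign_contig_completeness(calls: list[OrfCall]) -> str | None:
    """Assign the most complete ORF type found on one sequence.

    Order: complete > 5'-partial = 3'-partial > internal, with the tie
    between the two partial types broken toward 5'-partial (a fixed
    convention).  Returns None when there are no calls.
    """
    if not calls:
        return None
    tiebreak = {"complete": 1, "5prime_partial": 1, "3prime_partial": 0, "internal": 0}
    best = max(calls, key=lambda c: (COMPLETENESS_RANK[c.completeness],
                                     tiebreak[c.completeness]))
    return best.completeness


def best_orf(calls: list[OrfCall]) -> OrfCall | None:
    """The single best ORF: longest first, then most complete, then leftmost.

    Length-first follows the usual single-best-ORF convention of ORF
    predictors: the dominant reading frame of a transcript is the one with
    the longest open stretch, whatever its completeness.
    """
    if not calls:
        return None
    return max(
        calls,
        key=lambda c: (c.aa_length, COMPLETENESS_RANK[c.completeness], -c.start),
    )


def spliced_sequence(model, genome: dict[str, str]) -> str:
    """Extract the 5'->3' spliced transcript sequence from the genome."""
    from .errors import IntegrityError

    if model.contig not in genome:
        raise IntegrityError(f"contig {model.contig} missing from genome")
    seq = "".join(genome[model.contig][e.start : e.end] for e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq.upper()


def cds_improvement_report(
    reference_models,
    improved_models,
    genome: dict[str, str],
    min_aa: int = 100,
) -> dict[str, list[str]]:
    """Per-gene CDS improvement categories from reference to improved models.

    For each gene the best ORF over its reference transcripts is compared
    with the best ORF over its improved transcripts.  Categories:

    - ``gained_start``  — reference best ORF lacked an in-frame ATG
      (5'-partial or internal) and the improved best ORF has one;
    - ``gained_stop``   — reference best ORF lacked a stop (3'-partial or
      internal) and the improved best ORF has one;
    - ``new_complete``  — reference had no reportable ORF at all and the
      improved best ORF is complete;
    - ``unchanged``     — none of the above.

    A gene whose reference ORF was internal and whose improved ORF is
    complete gains both a start and a stop and carries both labels.
    """
    from .errors import IntegrityError

    by_gene_ref: dict[str, list] = {}
    for m in reference_models:
        by_gene_ref.setdefault(m.gene_id, []).append(m)
    by_gene_imp: dict[str, list] = {}
    for m in improved_models:
        by_gene_imp.setdefault(m.gene_id, []).append(m)

    report: dict[str, list[str]] = {}
    for gene_id, ref_models in by_gene_ref.items():
        imp_models = by_gene_imp.get(gene_id)
        if imp_models is None:
            continue
        for m in ref_models + imp_models:
            if m.contig not in genome:
                raise IntegrityError(f"gene {gene_id}: contig {m.contig} has no sequence")

        def gene_best(models):
            calls = []
            for m in models:
                calls.extend(
                    find_orfs(spliced_sequence(m, genome), m.transcript_id, min_aa)
                )
            return best_orf(calls)

        ref_best = gene_best(ref_models)
        imp_best = gene_best(imp_models)
        categories: list[str] = []
        has_start = lambda c: c is not None and c.completeness in ("complete", "3prime_partial")
        has_stop = lambda c: c is not None and c.completeness in ("complete", "5prime_partial")
        if ref_best is None:
            if imp_best is not None and imp_best.completeness == "complete":
                categories.append("new_complete")
        else:
            if not has_start(ref_best) and has_start(imp_best):
                categories.append("gained_start")
            if not has_stop(ref_best) and has_stop(imp_best):
                categories.append("gained_stop")
        report[gene_id] = categories or ["unchanged"]
    return report
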