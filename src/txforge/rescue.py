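"""Unmapped-read rescue and de novo contig post-processing.

Reads that fail genomic mapping are trimmed of poly-A/T tails and filtered
by length and GC content; assembled contigs then pass a fixed cascade:
per-stage TPM filter -> within-stage deduplication at 95% nucleotide
identity -> quality-gate hook -> coding classification -> cross-stage
deduplication -> final estimated-reads filter.  Deduplication follows the
greedy longest-first clustering convention of CD-HIT-EST: identity is
matches over the length of the shorter sequence, and each contig joins the
first cluster whose representative it matches at or above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .errors import IntegrityError
from .orfs import assign_contig_completeness, find_orfs, reverse_complement


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str
    stage: str = "PVS"
    tpm: float = 0.0
    estimated_reads: float = 0.0
    coding: bool | None = None
    completeness: str | None = None
    repeat_match: tuple[str, float, float] | None = None

    def __post_init__(self) -> None:
        if self.tpm < 0 or self.estimated_reads < 0:
            raise IntegrityError(f"contig {self.contig_id}: negative abundance")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)
    estimated_reads: float = 0.0


# ---------------------------------------------------------------------------
# Read rescue


def _trim_tail(seq: str, base: str, end: str, max_keep: int = 4) -> str:
    """Remove a terminal homopolymer run of ``base`` if longer than ``max_keep``."""
    if end == "3":
        run = len(seq) - len(seq.rstrip(base))
        return seq[: len(seq) - run] if run > max_keep else seq
    run = len(seq) - len(seq.lstrip(base))
    return seq[run:] if run > max_keep else seq


def trim_polya(seq: str) -> str:
    """Trim poly-A at the 3' end and poly-T at both ends (runs > 4)."""
    seq = _trim_tail(seq, "A", "3")
    seq = _trim_tail(seq, "T", "3")
    seq = _trim_tail(seq, "T", "5")
    return seq


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def rescue_filter_reads(
    reads: dict[str, str], min_length: int = 25, min_gc: float = 0.20
) -> dict[str, str]:
    """Trim poly-A/T tails, then keep reads with length > 25 and GC > 20%.

    Both thresholds are strict.
    """
    kept = {}
    for rid, seq in reads.items():
        trimmed = trim_polya(seq.upper())
        if len(trimmed) > min_length and gc_content(trimmed) > min_gc:
            kept[rid] = trimmed
    return kept


# ---------------------------------------------------------------------------
# Contig filters


def filter_contigs_by_tpm(
    contigs: list[ContigRecord], stage_tpm_min: float = 10.0
) -> list[ContigRecord]:
    """First-pass abundance filter: drop contigs with TPM < 10 (per stage)."""
    for c in contigs:
        if c.tpm is None:
            raise IntegrityError(f"contig {c.contig_id}: TPM not populated")
    return [c for c in contigs if c.tpm >= stage_tpm_min]


def filter_contigs_by_reads(
    contigs: list[ContigRecord], final_reads_min: float = 20.0
) -> list[ContigRecord]:
    """Final-pass filter: drop contigs with estimated reads < 20."""
    for c in contigs:
        if c.estimated_reads is None:
            raise IntegrityError(f"contig {c.contig_id}: estimated_reads not populated")
    return [c for c in contigs if c.estimated_reads >= final_reads_min]


# ---------------------------------------------------------------------------
# Greedy identity clustering


def pairwise_identity(a: str, b: str) -> float:
    """Nucleotide identity of the best alignment of the shorter inside the longer.

    Identity = matching positions / length of the shorter sequence, with
    indels and substitutions both counted as errors (the deduplication
    tool's convention for near-duplicates of unequal length).
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 1 - edlib.align(short, long_, mode="HW", task="distance")["editDistance"] / len(short)
    rc = reverse_complement(short)
    best_rc = 1 - edlib.align(rc, long_, mode="HW", task="distance")["editDistance"] / len(short)
    return max(best, best_rc, 0.0)


def greedy_cluster(
    contigs: list[ContigRecord], identity: float = 0.95
) -> list[Cluster]:
    """Greedy longest-first clustering at an identity threshold.

    Contigs are processed by decreasing length (ties by id); each joins the
    first existing cluster whose representative it matches at
    ``identity`` or better, otherwise founds a new cluster.  The
    representative is the longest member (the founder, by processing
    order); a cluster's estimated reads is the sum over its members.
    """
    by_id = {c.contig_id: c for c in contigs}
    order = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    clusters: list[Cluster] = []
    for c in order:
        placed = False
        for cl in clusters:
            if pairwise_identity(c.sequence, by_id[cl.representative].sequence) >= identity:
                cl.members.append(c.contig_id)
                cl.estimated_reads += c.estimated_reads
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=c.contig_id, members=[c.contig_id],
                        estimated_reads=c.estimated_reads)
            )
    for cl in clusters:
        cl.members.sort()
    return clusters


# ---------------------------------------------------------------------------
# Coding classification


def _translate(seq: str) -> str:
    table = {}
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    prot = []
    for j in range(0, len(seq) - 2, 3):
        prot.append(table.get(seq[j : j + 3], "X"))
    return "".join(prot)


def _protein_homology_hit(
    contig_seq: str,
    proteins: dict[str, str],
    seed_len: int = 8,
    min_aln_aa: int = 50,
    min_identity: float = 0.40,
) -> bool:
    """Translated seeded ungapped search: an exact amino-acid 8-mer seed is
    extended to the maximal ungapped overlap; a hit needs >= 50 aligned aa
    at >= 40% identity."""
    seeds: dict[str, list[tuple[str, int]]] = {}
    for pid, pseq in proteins.items():
        for i in range(len(pseq) - seed_len + 1):
            seeds.setdefault(pseq[i : i + seed_len], []).append((pid, i))
    frames = [contig_seq[f:] for f in range(3)]
    rc = reverse_complement(contig_seq)
    frames += [rc[f:] for f in range(3)]
    for frame_seq in frames:
        q = _translate(frame_seq)
        for i in range(len(q) - seed_len + 1):
            for pid, j in seeds.get(q[i : i + seed_len], ()):
                p = proteins[pid]
                left = min(i, j)
                right = min(len(q) - i, len(p) - j)
                qa = q[i - left : i + right]
                pa = p[j - left : j + right]
                if len(qa) >= min_aln_aa:
                    matches = sum(x == y for x, y in zip(qa, pa))
                    if matches / len(qa) >= min_identity:
                        return True
    return False


def classify_contig_coding(
    contig: ContigRecord,
    protein_set: dict[str, str] | None = None,
    min_aa: int = 100,
) -> ContigRecord:
    """Flag a contig as coding and assign its ORF completeness label.

    Coding = a six-frame ORF of >= ``min_aa`` codons exists, or (when a
    protein set is supplied) a translated homology hit is found.
    """
    calls = find_orfs(contig.sequence, contig.contig_id, min_aa=min_aa, strands="both")
    coding = bool(calls)
    if not coding and protein_set:
        coding = _protein_homology_hit(contig.sequence.upper(), protein_set)
    contig.coding = coding
    contig.completeness = assign_contig_completeness(calls)
    return contig


# ---------------------------------------------------------------------------
# Repeat novelty


def _best_local_segment(query: str, target: str, k: int = 11):
    """Best seeded ungapped local alignment segment (matches, length)."""
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        index.setdefault(target[j : j + k], []).append(j)
    best = (0, 0)  # matches, length
    seen: dict[int, int] = {}  # diagonal -> rightmost query end already extended
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            diag = i - j
            if seen.get(diag, -1) > i:
                continue  # seed lies inside a segment already extended
            li, lj = i, j
            while li > 0 and lj > 0 and query[li - 1] == target[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + k, j + k
            while ri < len(query) and rj < len(target) and query[ri] == target[rj]:
                ri += 1
                rj += 1
            seen[diag] = ri
            length = ri - li
            matches = length  # exact extension only
            if matches > best[0]:
                best = (matches, length)
    return best


def repeat_novelty_call(
    contig: ContigRecord,
    repeat_library: dict[str, str],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    min_hit_nt: int = 30,
) -> str:
    """Compare a contig with a repeat consensus library.

    ``known`` — best hit with identity >= ``min_identity`` and aligned
    coverage of the contig >= ``min_coverage``; ``novel`` — a hit exists but
    falls below either threshold (low identity or low alignment coverage);
    ``no_hit`` — no alignment segment of at least ``min_hit_nt`` matching
    bases against any library sequence.
    """
    import warnings

    seq = contig.sequence.upper()
    if not repeat_library:
        warnings.warn("empty repeat library: all contigs are no_hit")
        return "no_hit"
    best_id, best_cov, best_lib, best_matches = 0.0, 0.0, None, 0
    for lib_id, lib_seq in sorted(repeat_library.items()):
        for q in (seq, reverse_complement(seq)):
            matches, length = _best_local_segment(q, lib_seq.upper())
            if matches >= min_hit_nt and matches > best_matches:
                best_matches = matches
                best_id = matches / length if length else 0.0
                best_cov = length / len(seq)
                best_lib = lib_id
    if best_lib is None:
        contig.repeat_match = None
        return "no_hit"
    contig.repeat_match = (best_lib, best_id, best_cov)
    if best_id >= min_identity and best_cov >= min_coverage:
        return "known"
    return "novel"


# ---------------------------------------------------------------------------
# The full cascade


def rescue_cascade(
    contigs: list[ContigRecord],
    protein_set: dict[str, str] | None = None,
    stage_tpm_min: float = 10.0,
    cluster_identity: float = 0.95,
    final_reads_min: float = 20.0,
    min_aa: int = 100,
    quality_scores: dict[str, float] | None = None,
    quality_min: float | None = None,
) -> tuple[list[ContigRecord], list[Cluster]]:
    """Run the fixed contig filter cascade and return survivors + clusters.

    Order: per-stage TPM filter -> within-stage dedup -> quality gate
    (pass-through unless an external score table is supplied) -> coding
    classification -> cross-stage dedup -> final estimated-reads filter.
    """
    by_id = {c.contig_id: c for c in contigs}
    stages = sorted({c.stage for c in contigs})
    survivors: list[ContigRecord] = []
    for stage in stages:
        stage_contigs = [c for c in contigs if c.stage == stage]
        stage_contigs = filter_contigs_by_tpm(stage_contigs, stage_tpm_min)
        for cl in greedy_cluster(stage_contigs, cluster_identity):
            rep = by_id[cl.representative]
            rep.estimated_reads = cl.estimated_reads
            survivors.append(rep)
    if quality_scores is not None and quality_min is not None:
        survivors = [
            c for c in survivors
            if quality_scores.get(c.contig_id, float("inf")) >= quality_min
        ]
    for c in survivors:
        classify_contig_coding(c, protein_set, min_aa=min_aa)
    final_clusters = greedy_cluster(survivors, cluster_identity)
    reps = []
    for cl in final_clusters:
        rep = by_id[cl.representative]
        rep.estimated_reads = cl.estimated_reads
        reps.append(rep)
    reps = filter_contigs_by_reads(reps, final_reads_min)
    return reps, final_clusters
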