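"""Transfrag-vs-reference classification and annotation improvement.

Assembled transfrags are compared to the reference annotation by their
intron chains, in the spirit of the cuffcompare/gffcompare class codes:

- ``=``  full intron-chain match to a reference transcript on the same
  strand (boundary growth at the terminal exons does not break the match);
- ``j``  multi-exon transfrag sharing at least one splice junction — but
  not the whole chain — with a reference transcript on the same strand;
- ``u``  no exonic overlap with any reference transcript on either strand
  (intergenic/unknown);
- ``other`` every remaining overlap pattern; excluded downstream.

Junction equality is exact coordinate equality: no fuzz window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import IntegrityError
from .model import GenomicInterval, Transfrag, TranscriptModel


@dataclass(frozen=True)
class ClassCodeCall:
    transfrag_id: str
    code: str
    matched_reference_transcript: str | None = None
    matched_locus: str | None = None


@dataclass
class Locus:
    """A same-strand exon-overlap cluster of class-u transfrags."""

    locus_id: str
    members: list[str]
    span: GenomicInterval


@dataclass(frozen=True)
class ExtensionReport:
    gene_id: str
    five_prime_ext_bp: int
    three_prime_ext_bp: int

    @property
    def category(self) -> str:
        five, three = self.five_prime_ext_bp > 0, self.three_prime_ext_bp > 0
        if five and three:
            return "both"
        if five:
            return "5prime"
        if three:
            return "3prime"
        return "none"


class ReferenceIndex:
    """Exon interval index over a set of reference transcripts."""

    def __init__(self, models: list[TranscriptModel]):
        self.models = {m.transcript_id: m for m in models}
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.contig, IntervalTree())
            for e in m.exons:
                tree.addi(e.start, e.end, m.transcript_id)

    def overlapping(self, model: TranscriptModel, same_strand: bool | None = None):
        """Reference transcripts with >= 1 bp exonic overlap."""
        tree = self._trees.get(model.contig)
        if tree is None:
            return []
        hits = set()
        for e in model.exons:
            for iv in tree.overlap(e.start, e.end):
                hits.add(iv.data)
        out = []
        for tid in sorted(hits):
            ref = self.models[tid]
            if same_strand is None or (ref.strand == model.strand) == same_strand:
                out.append(ref)
        return out


def classify_transfrag(tf: Transfrag, index: ReferenceIndex) -> ClassCodeCall:
    """Assign a class code to one transfrag against the reference index."""
    model = tf.model
    for a, b in zip(model.exons, model.exons[1:]):
        if a.start > b.start:
            raise IntegrityError(f"transfrag {tf.transfrag_id}: unsorted exons")
    overlapping_any = index.overlapping(model)
    if not overlapping_any:
        return ClassCodeCall(tf.transfrag_id, "u")
    same_strand = [r for r in overlapping_any if r.strand == model.strand]
    chain = model.junctions
    # full intron-chain match (single-exon: both chains empty + exon overlap)
    for ref in same_strand:
        if chain == ref.junctions and (chain or not ref.is_multi_exon):
            return ClassCodeCall(
                tf.transfrag_id, "=",
                matched_reference_transcript=ref.transcript_id,
                matched_locus=ref.gene_id,
            )
    if model.is_multi_exon:
        chain_set = set(chain)
        best = None
        best_shared = 0
        for ref in same_strand:
            shared = len(chain_set & set(ref.junctions))
            if shared > best_shared:
                best, best_shared = ref, shared
        if best is not None:
            return ClassCodeCall(
                tf.transfrag_id, "j",
                matched_reference_transcript=best.transcript_id,
                matched_locus=best.gene_id,
            )
    return ClassCodeCall(tf.transfrag_id, "other")


def classify_all(transfrags: list[Transfrag], reference: list[TranscriptModel]):
    index = ReferenceIndex(reference)
    return [classify_transfrag(tf, index) for tf in transfrags]


def accept_novel_isoforms(
    calls: list[ClassCodeCall],
    transfrags: list[Transfrag],
    cpm_table: dict[str, dict[str, float]],
    min_support: int = 20,
    min_isoform_fraction: float = 0.4,
    min_cpm: float = 1.0,
) -> set[str]:
    """Filter class-j transfrags into accepted novel isoforms.

    A candidate must have >= ``min_support`` supporting read pairs, an
    abundance of at least ``min_isoform_fraction`` of the gene's major
    isoform (compared in the candidate's condition of maximal abundance),
    and CPM strictly above ``min_cpm`` in at least one condition.
    """
    tf_by_id = {tf.transfrag_id: tf for tf in transfrags}
    for c in calls:
        if c.transfrag_id not in tf_by_id:
            raise IntegrityError(f"call references unknown transfrag {c.transfrag_id}")
    # major-isoform abundance per gene and condition, over all gene members
    major: dict[str, dict[str, float]] = {}
    for c in calls:
        if c.code in ("=", "j") and c.matched_locus is not None:
            tf = tf_by_id[c.transfrag_id]
            g = major.setdefault(c.matched_locus, {})
            for cond, a in tf.abundance.items():
                g[cond] = max(g.get(cond, 0.0), a)
    accepted = set()
    for c in calls:
        if c.code != "j":
            continue
        tf = tf_by_id[c.transfrag_id]
        if tf.support_pairs < min_support:
            continue
        if not tf.abundance:
            continue
        # condition where this candidate is most abundant
        best_cond = max(sorted(tf.abundance), key=lambda k: tf.abundance[k])
        gene_major = major.get(c.matched_locus, {}).get(best_cond, 0.0)
        if tf.abundance[best_cond] < min_isoform_fraction * gene_major:
            continue
        cpm = cpm_table.get(c.transfrag_id, {})
        if not any(v > min_cpm for v in cpm.values()):
            continue
        accepted.add(c.transfrag_id)
    return accepted


def call_novel_genes(
    calls: list[ClassCodeCall],
    transfrags: list[Transfrag],
    min_support: int = 20,
) -> list[Locus]:
    """Cluster supported class-u transfrags into novel gene loci.

    Clustering is the transitive closure of same-strand exonic overlap;
    each locus becomes one novel gene with its members as isoforms.
    """
    tf_by_id = {tf.transfrag_id: tf for tf in transfrags}
    candidates = [
        tf_by_id[c.transfrag_id]
        for c in calls
        if c.code == "u" and tf_by_id[c.transfrag_id].support_pairs >= min_support
    ]
    candidates.sort(key=lambda tf: (tf.model.contig, tf.model.start, tf.transfrag_id))
    parent = {tf.transfrag_id: tf.transfrag_id for tf in candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if b.model.contig != a.model.contig or b.model.start >= a.model.end:
                break
            if b.model.strand != a.model.strand:
                continue
            if any(ea.overlaps(eb) for ea in a.model.exons for eb in b.model.exons):
                union(a.transfrag_id, b.transfrag_id)

    groups: dict[str, list[Transfrag]] = {}
    for tf in candidates:
        groups.setdefault(find(tf.transfrag_id), []).append(tf)
    loci = []
    ordered = sorted(
        groups.values(),
        key=lambda g: (g[0].model.contig, min(t.model.start for t in g)),
    )
    for i, members in enumerate(ordered, start=1):
        span = GenomicInterval(
            members[0].model.contig,
            min(t.model.start for t in members),
            max(t.model.end for t in members),
            members[0].model.strand,
        )
        loci.append(
            Locus(
                locus_id=f"XLOC_{i:06d}",
                members=sorted(t.transfrag_id for t in members),
                span=span,
            )
        )
    return loci


def count_expressed_genes(
    count_table,
    condition_of: dict[str, str],
    threshold: int = 40,
) -> dict[str, set[str]]:
    """Genes whose summed replicate read-pair counts reach ``threshold``.

    ``count_table`` is a genes x samples DataFrame; ``condition_of`` maps
    sample -> condition.  Returns condition -> expressed gene-id set.
    """
    if (count_table.values < 0).any():
        raise IntegrityError("negative counts in expression table")
    out: dict[str, set[str]] = {}
    for cond in sorted(set(condition_of.values())):
        samples = [s for s in count_table.columns if condition_of[s] == cond]
        totals = count_table[samples].sum(axis=1)
        out[cond] = set(totals.index[totals >= threshold])
    return out


def gene_span(models: list[TranscriptModel]) -> GenomicInterval:
    return GenomicInterval(
        models[0].contig,
        min(m.start for m in models),
        max(m.end for m in models),
        models[0].strand,
    )


def measure_extensions(
    improved: list[TranscriptModel],
    reference: list[TranscriptModel],
) -> list[ExtensionReport]:
    """Strand-aware 5'/3' gene-boundary growth from reference to improved.

    Extensions are measured on genomic termini of the per-gene span (union
    over isoforms).  Genes absent from the reference are skipped.
    """
    ref_genes: dict[str, list[TranscriptModel]] = {}
    for m in reference:
        ref_genes.setdefault(m.gene_id, []).append(m)
    imp_genes: dict[str, list[TranscriptModel]] = {}
    for m in improved:
        imp_genes.setdefault(m.gene_id, []).append(m)
    reports = []
    for gene_id in sorted(ref_genes):
        if gene_id not in imp_genes:
            continue
        ref = gene_span(ref_genes[gene_id])
        imp = gene_span(imp_genes[gene_id])
        if ref.strand == "-":
            five = max(0, imp.end - ref.end)
            three = max(0, ref.start - imp.start)
        else:
            five = max(0, ref.start - imp.start)
            three = max(0, imp.end - ref.end)
        reports.append(ExtensionReport(gene_id, five, three))
    return reports


def build_improved_annotation(
    reference: list[TranscriptModel],
    transfrags: list[Transfrag],
    calls: list[ClassCodeCall],
    accepted_isoforms: set[str],
) -> list[TranscriptModel]:
    """Reference with boundaries updated by '=' matches plus accepted novel isoforms.

    A class-'=' transfrag replaces the exon structure of its matched
    reference transcript (same intron chain, possibly grown terminal
    exons).  Accepted class-'j' transfrags are added as new isoforms of the
    matched gene.
    """
    tf_by_id = {tf.transfrag_id: tf for tf in transfrags}
    improved = {m.transcript_id: m for m in reference}
    extra: list[TranscriptModel] = []
    for c in calls:
        tf = tf_by_id[c.transfrag_id]
        if c.code == "=" and c.matched_reference_transcript in improved:
            ref = improved[c.matched_reference_transcript]
            new_exons = list(tf.model.exons)
            kept_cds = [
                cd for cd in ref.cds
                if any(e.start <= cd.start and cd.end <= e.end for e in new_exons)
            ]
            improved[ref.transcript_id] = TranscriptModel(
                transcript_id=ref.transcript_id,
                gene_id=ref.gene_id,
                exons=new_exons,
                cds=kept_cds,
                attributes=dict(ref.attributes),
            )
        elif c.code == "j" and c.transfrag_id in accepted_isoforms:
            extra.append(
                TranscriptModel(
                    transcript_id=c.transfrag_id,
                    gene_id=c.matched_locus,
                    exons=list(tf.model.exons),
                    attributes={"novel_isoform": "true"},
                )
            )
    return list(improved.values()) + extra
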