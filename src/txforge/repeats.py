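"""Repeat-class expression quantification.

Overlapping repeat copies of the same class and strand are merged into
regions (to reduce assignment ambiguity), short merged regions are dropped,
and read pairs are assigned fractionally: every genomic placement of a pair
contributes weight 1/n_hits to the features it overlaps.  Ambiguity is
decided at the pair level: a pair whose placements, taken together, touch
more than one element class (protein-coding gene vs any repeat class)
contributes its full weight to the ambiguous pool instead.  Assignment is
unstranded: a placement may hit a feature on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import IntegrityError
from .model import GenomicInterval, ReadPairAlignment, RepeatFeature, TranscriptModel

GENE_CLASS = "gene"


@dataclass
class MergedRepeatRegion:
    region_id: str
    interval: GenomicInterval
    repeat_class: str
    member_ids: list[str]

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class ClassExpressionSummary:
    repeat_class: str
    assigned_weight: dict[str, float] = field(default_factory=dict)  # sample -> weight

    @property
    def total(self) -> float:
        return sum(self.assigned_weight.values())


def merge_repeat_features(features: list[RepeatFeature]) -> list[MergedRepeatRegion]:
    """Merge strictly-overlapping same (contig, class, strand) repeat copies.

    Adjacent-but-not-overlapping copies stay separate; distinct classes are
    never merged even when they overlap.  Output sorted by contig, start.
    """
    groups: dict[tuple[str, str, str], list[RepeatFeature]] = {}
    for f in features:
        key = (f.interval.contig, f.repeat_class, f.interval.strand)
        groups.setdefault(key, []).append(f)
    regions: list[MergedRepeatRegion] = []
    for (contig, rclass, strand), members in groups.items():
        members.sort(key=lambda f: f.interval.start)
        cur = [members[0]]
        cur_end = members[0].interval.end
        for f in members[1:]:
            if f.interval.start < cur_end:  # strict overlap required
                cur.append(f)
                cur_end = max(cur_end, f.interval.end)
            else:
                regions.append(_make_region(contig, rclass, strand, cur))
                cur = [f]
                cur_end = f.interval.end
        regions.append(_make_region(contig, rclass, strand, cur))
    regions.sort(key=lambda r: (r.interval.contig, r.interval.start, r.repeat_class))
    for i, r in enumerate(regions, start=1):
        r.region_id = f"MRR_{i:06d}"
    return regions


def _make_region(contig, rclass, strand, members) -> MergedRepeatRegion:
    return MergedRepeatRegion(
        region_id="",
        interval=GenomicInterval(
            contig,
            min(f.interval.start for f in members),
            max(f.interval.end for f in members),
            strand,
        ),
        repeat_class=rclass,
        member_ids=[f.feature_id for f in members],
    )


def filter_regions_by_length(
    regions: list[MergedRepeatRegion], min_bp: int = 500
) -> list[MergedRepeatRegion]:
    """Keep merged regions strictly longer than ``min_bp`` (default 0.5 kb)."""
    return [r for r in regions if r.length > min_bp]


@dataclass
class AssignmentResult:
    class_summaries: dict[str, ClassExpressionSummary]
    region_counts: dict[str, dict[str, float]]  # region_id -> sample -> weight
    ambiguous_weight: dict[str, float]  # sample -> weight
    unassigned_weight: dict[str, float]  # sample -> weight
    total_pairs: dict[str, float]  # sample -> pair count


def _exon_tree(models: list[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.contig, IntervalTree())
        for e in m.exons:
            tree.addi(e.start, e.end, m.gene_id)
    return trees


def _region_tree(regions: list[MergedRepeatRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.interval.contig, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    return trees


def assign_pairs_fractional(
    alignments: list[ReadPairAlignment],
    gene_annotation: list[TranscriptModel],
    regions: list[MergedRepeatRegion],
    known_contigs: set[str] | None = None,
) -> AssignmentResult:
    """Fractional, ambiguity-aware assignment of read pairs to element classes.

    Each placement contributes 1/n_hits to every feature it overlaps (>= 1
    shared base with any aligned block).  A pair whose combined placements
    touch more than one element class is wholly ambiguous.  Weight is
    conserved per sample: assigned + ambiguous + unassigned = pair count.
    """
    gene_trees = _exon_tree(gene_annotation)
    region_trees = _region_tree(regions)
    if known_contigs is not None:
        for a in alignments:
            for b in a.blocks:
                if b.contig not in known_contigs:
                    raise IntegrityError(f"pair {a.pair_id}: unknown contig {b.contig}")

    pairs: dict[tuple[str, str], list[ReadPairAlignment]] = {}
    for a in alignments:
        pairs.setdefault((a.sample, a.pair_id), []).append(a)

    summaries: dict[str, ClassExpressionSummary] = {}
    region_counts: dict[str, dict[str, float]] = {}
    ambiguous: dict[str, float] = {}
    unassigned: dict[str, float] = {}
    totals: dict[str, float] = {}

    for (sample, _pid), placements in pairs.items():
        totals[sample] = totals.get(sample, 0.0) + 1.0
        n_hits = placements[0].n_hits
        # what does each placement touch?
        touched_classes: set[str] = set()
        placement_hits: list[tuple[ReadPairAlignment, set[str], list]] = []
        for pl in placements:
            classes: set[str] = set()
            region_hits = []
            for b in pl.blocks:
                gt = gene_trees.get(b.contig)
                if gt is not None and gt.overlap(b.start, b.end):
                    classes.add(GENE_CLASS)
                rt = region_trees.get(b.contig)
                if rt is not None:
                    for iv in rt.overlap(b.start, b.end):
                        classes.add(iv.data.repeat_class)
                        region_hits.append(iv.data)
            touched_classes |= classes
            placement_hits.append((pl, classes, region_hits))
        if len(touched_classes) > 1:
            ambiguous[sample] = ambiguous.get(sample, 0.0) + 1.0
            continue
        if not touched_classes:
            unassigned[sample] = unassigned.get(sample, 0.0) + 1.0
            continue
        the_class = next(iter(touched_classes))
        w = 0.0
        for pl, classes, region_hits in placement_hits:
            if not classes:
                continue
            w += 1.0 / n_hits
            for r in {id(x): x for x in region_hits}.values():
                region_counts.setdefault(r.region_id, {})
                region_counts[r.region_id][sample] = (
                    region_counts[r.region_id].get(sample, 0.0) + 1.0 / n_hits
                )
        s = summaries.setdefault(the_class, ClassExpressionSummary(the_class))
        s.assigned_weight[sample] = s.assigned_weight.get(sample, 0.0) + w
        # placements not overlapping anything leave part of the pair unassigned
        if w < 1.0 - 1e-12:
            unassigned[sample] = unassigned.get(sample, 0.0) + (1.0 - w)
    return AssignmentResult(
        class_summaries=summaries,
        region_counts=region_counts,
        ambiguous_weight=ambiguous,
        unassigned_weight=unassigned,
        total_pairs=totals,
    )
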