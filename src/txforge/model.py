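"""Core domain types.

All genomic coordinates are held in the 0-based half-open convention;
conversion to/from the 1-based inclusive convention of GTF/GFF text happens
exactly once, inside :mod:`txforge.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IntegrityError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a named contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise IntegrityError("interval with empty contig name")
        if self.start >= self.end:
            raise IntegrityError(
                f"interval {self.contig}:{self.start}-{self.end} has start >= end"
            )
        if self.strand not in STRANDS:
            raise IntegrityError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap (>= 1 shared base); strand is not consulted."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A stranded exon chain with optional CDS sub-intervals.

    Exons are kept sorted by genomic start, non-overlapping, all on one
    contig and strand.  ``cds`` intervals, when present, must lie inside the
    exon union.  ``junctions`` (the intron chain) is the ordered list of
    (donor, acceptor) genomic coordinates; two transcripts are structurally
    identical iff their intron chains are identical.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise IntegrityError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        contigs = {e.contig for e in self.exons}
        if len(contigs) != 1:
            raise IntegrityError(
                f"transcript {self.transcript_id} has exons on contigs {sorted(contigs)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise IntegrityError(
                f"transcript {self.transcript_id} mixes strands {sorted(strands)}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise IntegrityError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        for c in sorted(self.cds, key=lambda x: x.start):
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise IntegrityError(
                    f"transcript {self.transcript_id}: CDS {c.start}-{c.end} "
                    "outside exon union"
                )
        self.cds = sorted(self.cds, key=lambda c: c.start)

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron (donor_end, acceptor_start) pairs in genome order."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1


@dataclass
class RepeatFeature:
    """A classed, stranded repeat copy (e.g. Tc1-mariner, Helitron)."""

    feature_id: str
    interval: GenomicInterval
    repeat_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise IntegrityError(f"repeat {self.feature_id} lacks a class")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class ReadPairAlignment:
    """One genomic placement of a paired fragment.

    A multi-mapping pair appears as several placements sharing ``pair_id``
    and ``n_hits``; each placement carries weight ``1 / n_hits`` in
    fractional counting.
    """

    pair_id: str
    sample: str
    blocks: list[GenomicInterval]
    n_hits: int = 1
    both_ends_aligned: bool = True
    same_contig_strand: bool = True

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise IntegrityError(f"pair {self.pair_id}: n_hits must be >= 1")
        if self.both_ends_aligned and not self.blocks:
            raise IntegrityError(
                f"pair {self.pair_id}: both ends aligned but no blocks"
            )

    @property
    def contig(self) -> str:
        return self.blocks[0].contig


@dataclass
class Transfrag:
    """An assembled transcript with read-pair support and abundances.

    ``abundance`` maps condition name -> estimated counts; ``cpm`` is filled
    by the quantification stage.
    """

    model: TranscriptModel
    support_pairs: int = 0
    abundance: dict[str, float] = field(default_factory=dict)
    cpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support_pairs < 0:
            raise IntegrityError(
                f"transfrag {self.transfrag_id}: negative support"
            )
        for cond, a in self.abundance.items():
            if a < 0:
                raise IntegrityError(
                    f"transfrag {self.transfrag_id}: negative abundance in {cond}"
                )

    @property
    def transfrag_id(self) -> str:
        return self.model.transcript_id
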