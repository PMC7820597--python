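"""Synthetic two-stage ovarian transcriptome experiment with planted truth.

The generator emulates the study design the pipeline targets: two
conditions (previtellogenic stage, PVS, and mature egg) with two
biological replicates each.  It builds a random genome, plants multi-exon
protein-coding genes (5'UTR + ATG...stop CDS + 3'UTR), then degrades a
copy of that truth annotation the way an incomplete reference annotation
is degraded in the wild: genes and secondary isoforms are dropped and UTRs
are truncated at the terminal exons, sometimes deep enough to cut into the
CDS and remove the start or stop codon.  Negative-binomial counts with
planted maternal-deposition fold changes ("up" = higher in Egg), exact
assembler transfrags, a repeat landscape with multi-mapping read pairs and
an unmapped-read pool complete the dataset.  Every planted fact is
recorded in a :class:`TruthLedger`, the recovery target of the test suite.

Each stage derives its own child seed from ``config.seed``, so outputs are
byte-identical across runs and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    GenomicInterval,
    ReadPairAlignment,
    RepeatFeature,
    Transfrag,
    TranscriptModel,
)
from .orfs import reverse_complement
from .rescue import ContigRecord

CONDITIONS = ("PVS", "Egg")
SAMPLES = ("PVS_1", "PVS_2", "Egg_1", "Egg_2")
CONDITION_OF = {"PVS_1": "PVS", "PVS_2": "PVS", "Egg_1": "Egg", "Egg_2": "Egg"}

_BASES = np.array(list("ACGT"))
# sense codons excluding ATG and stops, so a planted CDS has exactly one
# in-frame start and one in-frame stop
_SAFE_CODONS = [
    b1 + b2 + b3
    for b1 in "ACGT"
    for b2 in "ACGT"
    for b3 in "ACGT"
    if b1 + b2 + b3 not in ("ATG", "TAA", "TAG", "TGA")
]


@dataclass
class RepeatClassSpec:
    name: str
    copies: int
    mean_length: int = 800
    overlap_fraction: float = 0.3  # fraction of copies planted as overlapping pairs


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 400_000
    gc: float = 0.5
    n_genes: int = 200
    p_second_isoform: float = 0.4
    p_drop_gene: float = 0.1
    p_drop_isoform: float = 0.3
    p_truncate_5p: float = 0.3
    p_truncate_3p: float = 0.3
    p_trunc_into_cds: float = 0.4
    nb_mean_log: float = np.log(500.0)
    nb_mean_sd: float = 0.5
    nb_dispersion: float = 0.05
    p_de: float = 0.1
    de_log2fc: float = 2.0
    capture_rate: float = 0.5
    noise_transfrag_fraction: float = 0.05
    repeat_classes: list[RepeatClassSpec] = field(
        default_factory=lambda: [
            RepeatClassSpec("Tc1-mariner", 30, 900),
            RepeatClassSpec("Helitron", 14, 700),
            RepeatClassSpec("R1", 10, 800),
            RepeatClassSpec("Satellite", 10, 450),
            RepeatClassSpec("Unknown", 8, 600),
        ]
    )
    pairs_per_repeat_copy: float = 12.0
    repeat_multimap_fraction: float = 0.3
    read_length: int = 100
    reads_per_dropped_gene: int = 30
    polyA_fraction: float = 0.1
    lowgc_fraction: float = 0.1

    def validate(self) -> None:
        for name in (
            "p_second_isoform", "p_drop_gene", "p_drop_isoform", "p_truncate_5p",
            "p_truncate_3p", "p_trunc_into_cds", "p_de", "capture_rate",
            "noise_transfrag_fraction", "repeat_multimap_fraction",
            "polyA_fraction", "lowgc_fraction", "gc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.polyA_fraction + self.lowgc_fraction > 1.0:
            raise ConfigError("junk read fractions sum above 1")
        if self.contig_length <= 0 or self.read_length <= 0:
            raise ConfigError("lengths must be positive")
        if self.n_contigs < 0 or self.n_genes < 0:
            raise ConfigError("counts must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return np.random.default_rng(ss)


@dataclass
class TruthLedger:
    dropped_genes: set[str] = field(default_factory=set)
    dropped_isoforms: set[str] = field(default_factory=set)
    truncations: dict[str, tuple[int, int]] = field(default_factory=dict)
    cds_truncated_5p: set[str] = field(default_factory=set)
    cds_truncated_3p: set[str] = field(default_factory=set)
    planted_de: dict[str, tuple[str, float]] = field(default_factory=dict)
    repeat_copies: dict[str, list[str]] = field(default_factory=dict)
    repeat_clusters: dict[str, list[list[str]]] = field(default_factory=dict)
    orf_truth: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        for k in ("dropped_genes", "dropped_isoforms", "cds_truncated_5p",
                  "cds_truncated_3p"):
            d[k] = sorted(d[k])
        return d


# ---------------------------------------------------------------------------
# Genome


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random i.i.d. genome at the configured GC content."""
    config.validate()
    rng = config.rng("genome")
    gc = config.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    for i in range(config.n_contigs):
        bases = rng.choice(_BASES, size=config.contig_length, p=probs)
        genome[f"contig_{i + 1}"] = "".join(bases)
    return genome


# ---------------------------------------------------------------------------
# Annotation pair


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _scrub_spurious_atg(spliced: str, start_pos: int) -> str:
    """Remove every ATG trinucleotide except the planted start codon.

    The G of each spurious occurrence is set to C: no stop codon contains
    C, so the change can neither create an in-frame stop inside the CDS nor
    a new ATG.  This makes the planted ORF the unique ATG-initiated ORF of
    the transcript, so ORF-level truncation recovery is unambiguous.
    """
    seq = list(spliced)
    i = spliced.find("ATG")
    while i != -1:
        if i != start_pos:
            seq[i + 2] = "C"
        i = "".join(seq).find("ATG", i + 1)
    return "".join(seq)


def _spliced_to_genomic(exons, strand, sp_start, sp_end):
    """Map a spliced [sp_start, sp_end) range to genomic intervals."""
    # exon order along the transcript
    ordered = exons if strand == "+" else list(reversed(exons))
    out = []
    offset = 0
    for e in ordered:
        elen = e.end - e.start
        lo = max(sp_start, offset)
        hi = min(sp_end, offset + elen)
        if lo < hi:
            if strand == "+":
                out.append(GenomicInterval(e.contig, e.start + (lo - offset),
                                           e.start + (hi - offset), strand))
            else:
                out.append(GenomicInterval(e.contig, e.end - (hi - offset),
                                           e.end - (lo - offset), strand))
        offset += elen
    return sorted(out, key=lambda iv: iv.start)


def generate_annotation_pair(
    genome: dict[str, str], config: SimulationConfig
) -> tuple[list[TranscriptModel], list[TranscriptModel], TruthLedger]:
    """Plant genes into the genome; return (truth, degraded reference, ledger).

    Genes are placed non-overlapping (any strand) with intergenic gaps.  The
    planted CDS contains exactly one in-frame ATG and stop, so ORF-level
    recovery of truncation damage is unambiguous.  The genome map is
    modified in place where gene sequence is written.
    """
    config.validate()
    rng = config.rng("annotation")
    ledger = TruthLedger()
    truth: list[TranscriptModel] = []
    reference: list[TranscriptModel] = []

    contig_names = sorted(genome)
    cursor = {c: 2000 for c in contig_names}
    ci = 0
    for gi in range(config.n_genes):
        gene_id = f"GENE{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(200, 401))
        n_codons = int(rng.integers(150, 301))
        cds_len = 3 * (n_codons + 1)  # includes stop codon
        u3 = int(rng.integers(300, 601))
        spliced = (
            _random_seq(rng, u5)
            + "ATG"
            + "".join(rng.choice(_SAFE_CODONS, size=n_codons - 1))
            + str(rng.choice(["TAA", "TAG"]))
            + _random_seq(rng, u3)
        )
        spliced = _scrub_spurious_atg(spliced, u5)
        total = len(spliced)
        assert total == u5 + cds_len + u3

        # exon structure: first exon holds the whole 5'UTR plus >=120 bp of
        # CDS; last exon holds >=120 bp of CDS plus the 3'UTR; the middle is
        # split into 1-3 internal exons
        first_len = u5 + int(rng.integers(120, 200))
        last_len = u3 + int(rng.integers(120, 200))
        middle = total - first_len - last_len
        n_internal = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, middle), size=n_internal - 1,
                                  replace=False)) if n_internal > 1 else np.array([], int)
        internal_lens = np.diff(np.concatenate(([0], cuts, [middle]))).tolist()
        exon_lens = [first_len] + internal_lens + [last_len]
        intron_lens = [int(rng.integers(100, 501)) for _ in range(len(exon_lens) - 1)]

        gene_span = sum(exon_lens) + sum(intron_lens)
        # find a contig with room
        placed = False
        for _ in range(len(contig_names)):
            contig = contig_names[ci % len(contig_names)]
            if cursor[contig] + gene_span + 2000 <= config.contig_length:
                placed = True
                break
            ci += 1
        if not placed:
            raise ConfigError(
                f"genome too short to place {config.n_genes} genes"
            )
        start = cursor[contig] + int(rng.integers(200, 1200))
        cursor[contig] = start + gene_span + 800
        ci += 1

        # genomic exon intervals (genome order)
        exons = []
        pos = start
        tx_order_lens = exon_lens if strand == "+" else list(reversed(exon_lens))
        for k, elen in enumerate(tx_order_lens):
            exons.append(GenomicInterval(contig, pos, pos + elen, strand))
            if k < len(intron_lens):
                pos += elen + intron_lens[k]
        # write gene sequence into the genome
        plus_seq = spliced if strand == "+" else reverse_complement(spliced)
        seq = genome[contig]
        offset = 0
        for e in sorted(exons, key=lambda x: x.start):
            elen = e.end - e.start
            seq = seq[: e.start] + plus_seq[offset : offset + elen] + seq[e.end :]
            offset += elen
        genome[contig] = seq

        exons = sorted(exons, key=lambda e: e.start)
        cds_ivs = _spliced_to_genomic(exons, strand, u5, u5 + cds_len)
        tid = f"{gene_id}.1"
        primary = TranscriptModel(tid, gene_id, exons, cds=cds_ivs,
                                  attributes={"u5": str(u5), "cds_len": str(cds_len)})
        isoforms = [primary]
        ledger.orf_truth[tid] = "complete"
        if len(exons) >= 4 and rng.random() < config.p_second_isoform:
            # skipped internal exon (never the first or last)
            skip = int(rng.integers(1, len(exons) - 1))
            alt_exons = [e for k, e in enumerate(exons) if k != skip]
            tid2 = f"{gene_id}.2"
            isoforms.append(TranscriptModel(tid2, gene_id, alt_exons))
            ledger.orf_truth[tid2] = "complete" if all(
                not (e.start <= c.start and c.end <= e.end)
                for c in cds_ivs for e in [exons[skip]]
            ) else "unknown"

        truth.extend(isoforms)

        # --- degradation into the reference
        if rng.random() < config.p_drop_gene:
            ledger.dropped_genes.add(gene_id)
            continue
        kept = [isoforms[0]]
        for iso in isoforms[1:]:
            if rng.random() < config.p_drop_isoform:
                ledger.dropped_isoforms.add(iso.transcript_id)
            else:
                kept.append(iso)

        t5 = t3 = 0
        cut5 = cut3 = False
        first_exon_len = exon_lens[0]
        last_exon_len = exon_lens[-1]
        if rng.random() < config.p_truncate_5p:
            if rng.random() < config.p_trunc_into_cds:
                t5 = u5 + int(rng.integers(10, 91))  # removes the ATG
                cut5 = True
            else:
                t5 = int(rng.integers(50, max(51, u5 - 10)))
            t5 = min(t5, first_exon_len - 50)
        if rng.random() < config.p_truncate_3p:
            if rng.random() < config.p_trunc_into_cds:
                t3 = u3 + int(rng.integers(10, 91))  # removes the stop
                cut3 = True
            else:
                t3 = int(rng.integers(50, max(51, u3 - 10)))
            t3 = min(t3, last_exon_len - 50)
        if t5 or t3:
            ledger.truncations[gene_id] = (t5, t3)
            if cut5:
                ledger.cds_truncated_5p.add(gene_id)
            if cut3:
                ledger.cds_truncated_3p.add(gene_id)
        for iso in kept:
            reference.append(_truncate_model(iso, t5, t3))
    return truth, reference, ledger


def _truncate_model(model: TranscriptModel, t5: int, t3: int) -> TranscriptModel:
    """Trim t5/t3 bp of spliced sequence off the transcript termini.

    Truncation is confined to the terminal exons (guaranteed by
    construction in the generator)."""
    exons = [GenomicInterval(e.contig, e.start, e.end, e.strand) for e in model.exons]
    strand = model.strand
    trim_left = t5 if strand == "+" else t3  # genomic-left trim amount
    trim_right = t3 if strand == "+" else t5
    first, last = exons[0], exons[-1]
    exons[0] = GenomicInterval(first.contig, first.start + trim_left, first.end, strand)
    exons[-1] = GenomicInterval(last.contig, last.start, last.end - trim_right, strand)
    new_start, new_end = exons[0].start, exons[-1].end
    cds = []
    for c in model.cds:
        s, e = max(c.start, new_start), min(c.end, new_end)
        if s < e:
            cds.append(GenomicInterval(c.contig, s, e, strand))
    return TranscriptModel(model.transcript_id, model.gene_id, exons, cds=cds,
                           attributes=dict(model.attributes))


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    truth: list[TranscriptModel], config: SimulationConfig, ledger: TruthLedger
) -> pd.DataFrame:
    """NB counts per transcript for the 2x2 design, with planted DE.

    DE is planted per gene; "up" means the Egg mean is scaled by
    2**log2fc (maternal deposition), "down" the reverse.
    """
    config.validate()
    rng = config.rng("counts")
    genes = sorted({m.gene_id for m in truth})
    gene_mean = {
        g: float(np.exp(rng.normal(config.nb_mean_log, config.nb_mean_sd)))
        for g in genes
    }
    for g in genes:
        if rng.random() < config.p_de:
            direction = "up" if rng.random() < 0.5 else "down"
            ledger.planted_de[g] = (direction, config.de_log2fc)
    rows = {}
    for m in sorted(truth, key=lambda m: m.transcript_id):
        iso_share = 0.7 if m.transcript_id.endswith(".1") else 0.3
        base = gene_mean[m.gene_id] * iso_share
        means = {c: base for c in CONDITIONS}
        if m.gene_id in ledger.planted_de:
            direction, lfc = ledger.planted_de[m.gene_id]
            scale = 2.0 ** lfc
            if direction == "up":
                means["Egg"] *= scale
            else:
                means["PVS"] *= scale
        row = []
        for s in SAMPLES:
            mu = means[CONDITION_OF[s]]
            row.append(_nb_draw(rng, mu, config.nb_dispersion))
        rows[m.transcript_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SAMPLES))


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    if mu <= 0:
        return 0
    if alpha < 1e-9:
        return int(rng.poisson(mu))
    n = 1.0 / alpha
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


# ---------------------------------------------------------------------------
# Transfrags


def simulate_transfrags(
    truth: list[TranscriptModel],
    counts: pd.DataFrame,
    config: SimulationConfig,
) -> list[Transfrag]:
    """Exact-structure transfrags for every expressed truth transcript.

    Support read-pairs are the total counts scaled by the capture rate;
    per-condition abundance is the summed replicate counts.  A configurable
    fraction of sub-threshold single-exon noise transfrags is planted in
    intergenic space.
    """
    config.validate()
    rng = config.rng("transfrags")
    transfrags = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for m in truth:
        occupied.setdefault(m.contig, []).append((m.start, m.end))
    for m in sorted(truth, key=lambda m: m.transcript_id):
        if m.transcript_id not in counts.index:
            continue
        row = counts.loc[m.transcript_id]
        total = float(row.sum())
        if total <= 0:
            continue
        abundance = {
            c: float(sum(row[s] for s in SAMPLES if CONDITION_OF[s] == c))
            for c in CONDITIONS
        }
        model = TranscriptModel(
            transcript_id=f"TF_{m.transcript_id}",
            gene_id=f"TFLOC_{m.gene_id}",
            exons=[GenomicInterval(e.contig, e.start, e.end, e.strand)
                   for e in m.exons],
        )
        transfrags.append(
            Transfrag(
                model=model,
                support_pairs=int(round(total * config.capture_rate)),
                abundance=abundance,
            )
        )
    n_noise = int(round(len(transfrags) * config.noise_transfrag_fraction))
    contigs = sorted(occupied) or [f"contig_{i+1}" for i in range(config.n_contigs)]
    for k in range(n_noise):
        for _ in range(100):
            contig = contigs[int(rng.integers(0, len(contigs)))]
            length = int(rng.integers(200, 800))
            start = int(rng.integers(0, config.contig_length - length))
            if all(
                start + length <= s or e <= start
                for s, e in occupied.get(contig, [])
            ):
                break
        else:
            continue
        occupied.setdefault(contig, []).append((start, start + length))
        model = TranscriptModel(
            transcript_id=f"TF_noise{k + 1:04d}",
            gene_id=f"TFLOC_noise{k + 1:04d}",
            exons=[GenomicInterval(contig, start, start + length,
                                   "+" if rng.random() < 0.5 else "-")],
        )
        transfrags.append(
            Transfrag(model=model, support_pairs=int(rng.integers(1, 20)),
                      abundance={c: float(rng.integers(1, 20)) for c in CONDITIONS})
        )
    return transfrags


def expressed_gene_ids(transfrags: list[Transfrag], min_support: int = 20) -> set[str]:
    """Truth gene ids with at least one transfrag passing the support cutoff."""
    out = set()
    for tf in transfrags:
        if tf.support_pairs >= min_support and tf.model.gene_id.startswith("TFLOC_GENE"):
            out.add(tf.model.gene_id.removeprefix("TFLOC_"))
    return out


# ---------------------------------------------------------------------------
# Repeat landscape


def simulate_repeat_landscape(
    genome: dict[str, str],
    config: SimulationConfig,
    ledger: TruthLedger | None = None,
) -> tuple[list[RepeatFeature], list[ReadPairAlignment]]:
    """Plant repeat copies (some overlapping within class) and read pairs.

    Pairs are unique or multi-mapped across copies of the same class.
    Copies are placed uniformly, so some overlap planted genes; pairs in
    those copies touch two element classes and become ambiguous at
    assignment time.
    """
    config.validate()
    rng = config.rng("repeats")
    contigs = sorted(genome)
    if not contigs:
        return [], []
    features: list[RepeatFeature] = []
    alignments: list[ReadPairAlignment] = []
    fid = 0
    pid = 0
    for spec in config.repeat_classes:
        if spec.copies <= 0:
            continue
        class_features: list[RepeatFeature] = []
        clusters: list[list[str]] = []
        i = 0
        while i < spec.copies:
            contig = contigs[int(rng.integers(0, len(contigs)))]
            length = max(200, int(rng.normal(spec.mean_length, spec.mean_length / 4)))
            start = int(rng.integers(0, max(1, len(genome[contig]) - 3 * length)))
            strand = "+" if rng.random() < 0.5 else "-"
            fid += 1
            f1 = RepeatFeature(f"rep{fid:05d}",
                               GenomicInterval(contig, start, start + length, strand),
                               spec.name)
            class_features.append(f1)
            i += 1
            if i < spec.copies and rng.random() < spec.overlap_fraction:
                # plant an overlapping same-class, same-strand partner
                ov_start = start + length // 2
                fid += 1
                f2 = RepeatFeature(f"rep{fid:05d}",
                                   GenomicInterval(contig, ov_start,
                                                   ov_start + length, strand),
                                   spec.name)
                class_features.append(f2)
                clusters.append([f1.feature_id, f2.feature_id])
                i += 1
            else:
                clusters.append([f1.feature_id])
        features.extend(class_features)
        if ledger is not None:
            ledger.repeat_copies[spec.name] = [f.feature_id for f in class_features]
            ledger.repeat_clusters[spec.name] = clusters

        for sample in SAMPLES:
            n_pairs = int(rng.poisson(config.pairs_per_repeat_copy * len(class_features)))
            for _ in range(n_pairs):
                pid += 1
                r = rng.random()
                if r < config.repeat_multimap_fraction and len(class_features) > 1:
                    n_hits = int(rng.integers(2, min(5, len(class_features) + 1)))
                    homes = rng.choice(len(class_features), size=n_hits, replace=False)
                    for h in homes:
                        alignments.append(
                            _pair_in(rng, class_features[int(h)], f"rp{pid:07d}",
                                     sample, n_hits, config.read_length)
                        )
                else:
                    home = class_features[int(rng.integers(0, len(class_features)))]
                    alignments.append(
                        _pair_in(rng, home, f"rp{pid:07d}", sample, 1,
                                 config.read_length)
                    )
    return features, alignments


def _pair_in(rng, feature: RepeatFeature, pair_id: str, sample: str,
             n_hits: int, read_length: int) -> ReadPairAlignment:
    iv = feature.interval
    span = max(len(iv) - 2 * read_length - 50, 1)
    s1 = iv.start + int(rng.integers(0, span))
    b1 = GenomicInterval(iv.contig, s1, min(s1 + read_length, iv.end), iv.strand)
    s2 = min(b1.end + 50, iv.end - 1)
    b2 = GenomicInterval(iv.contig, s2, min(s2 + read_length, iv.end + read_length),
                         iv.strand)
    return ReadPairAlignment(pair_id=pair_id, sample=sample, blocks=[b1, b2],
                             n_hits=n_hits)


# ---------------------------------------------------------------------------
# Unmapped pool and de novo contigs


def spliced_seq(model: TranscriptModel, genome: dict[str, str]) -> str:
    from .orfs import spliced_sequence

    return spliced_sequence(model, genome)


def simulate_unmapped_pool(
    truth: list[TranscriptModel],
    genome: dict[str, str],
    ledger: TruthLedger,
    config: SimulationConfig,
) -> dict[str, str]:
    """Unmapped-read pool: dropped-gene fragments plus poly-A and low-GC junk.

    Read-id prefixes (``gene|``, ``polyA|``, ``lowgc|``) partition the pool
    exactly into the three source categories.
    """
    config.validate()
    rng = config.rng("unmapped")
    reads: dict[str, str] = {}
    dropped_models = [m for m in truth if m.gene_id in ledger.dropped_genes]
    rl = config.read_length
    n_gene_reads = 0
    for m in sorted(dropped_models, key=lambda m: m.transcript_id):
        seq = spliced_seq(m, genome)
        if len(seq) <= rl:
            continue
        for k in range(config.reads_per_dropped_gene):
            start = int(rng.integers(0, len(seq) - rl))
            reads[f"gene|{m.transcript_id}|{k}"] = seq[start : start + rl]
            n_gene_reads += 1
    denom = max(1.0 - config.polyA_fraction - config.lowgc_fraction, 1e-9)
    n_polya = int(round(n_gene_reads * config.polyA_fraction / denom))
    n_lowgc = int(round(n_gene_reads * config.lowgc_fraction / denom))
    if n_gene_reads == 0:
        scale = 200 if (config.polyA_fraction or config.lowgc_fraction) else 0
        n_polya = int(round(scale * config.polyA_fraction))
        n_lowgc = int(round(scale * config.lowgc_fraction))
    for k in range(n_polya):
        body = _random_seq(rng, rl - 12)
        tail = ("A" if rng.random() < 0.5 else "T") * 12
        reads[f"polyA|{k}"] = body + tail
    for k in range(n_lowgc):
        at = rng.choice(np.array(list("AT")), size=rl - 10)
        gc = rng.choice(np.array(list("GC")), size=10)
        seq = np.concatenate([at, gc])
        rng.shuffle(seq)
        reads[f"lowgc|{k}"] = "".join(seq)
    return reads


def simulate_denovo_contigs(
    truth: list[TranscriptModel],
    genome: dict[str, str],
    ledger: TruthLedger,
    counts: pd.DataFrame,
    config: SimulationConfig,
) -> list[ContigRecord]:
    """De novo contigs: dropped-gene transcripts plus non-coding junk.

    Only the primary (CDS-bearing) isoform of each dropped gene is
    assembled — the dominant-isoform simplification of a de novo
    assembler.  Dropped-gene contigs inherit abundance from the count
    table; junk contigs are random sequence with sub-threshold TPM so the
    filter cascade removes them.
    """
    rng = config.rng("contigs")
    contigs = []
    for m in sorted(truth, key=lambda m: m.transcript_id):
        if m.gene_id not in ledger.dropped_genes or not m.transcript_id.endswith(".1"):
            continue
        row = counts.loc[m.transcript_id] if m.transcript_id in counts.index else None
        total = float(row.sum()) if row is not None else 0.0
        contigs.append(
            ContigRecord(
                contig_id=f"DN_{m.transcript_id}",
                sequence=spliced_seq(m, genome),
                stage="Egg" if rng.random() < 0.5 else "PVS",
                tpm=max(10.0, total / 10.0),
                estimated_reads=total * config.capture_rate,
            )
        )
    n_junk = max(2, len(contigs) // 3)
    for k in range(n_junk):
        contigs.append(
            ContigRecord(
                contig_id=f"DN_junk{k + 1:03d}",
                sequence=_random_seq(rng, int(rng.integers(300, 600))),
                stage="PVS",
                tpm=float(rng.uniform(0.1, 9.9)),
                estimated_reads=float(rng.uniform(1, 15)),
            )
        )
    return contigs
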