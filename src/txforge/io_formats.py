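"""Readers and writers for the external text formats the pipeline touches.

GTF/GFF text is 1-based inclusive; everything in memory is 0-based
half-open.  The conversion happens here and nowhere else, so a GTF round
trip through :func:`read_gtf` / :func:`write_gtf` is byte-stable for
canonical input.  Parsers reject malformed records with a line-numbered
:class:`~txforge.errors.ParseError`; they never silently repair them.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import IntegrityError, ParseError
from .model import (
    GenomicInterval,
    ReadPairAlignment,
    RepeatFeature,
    Transfrag,
    TranscriptModel,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_FASTA_ALPHABET = set("ACGTN")


def _as_stream(source) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if not attrs:
        raise ParseError(f"line {lineno}: unparseable GTF attribute field {field!r}")
    return attrs


def read_gtf(source) -> list[TranscriptModel]:
    """Parse GTF2.2 exon/CDS features into transcript models.

    Features other than ``exon`` and ``CDS`` are ignored.  Both gene_id and
    transcript_id attributes are mandatory.  Extra attributes of the first
    exon line are kept on the model.
    """
    stream = _as_stream(source)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    attrs_of: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
        contig, _src, ftype, start, end, _score, strand, _frame, attr_field = fields
        if ftype not in ("exon", "CDS"):
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        attrs = _parse_gtf_attributes(attr_field, lineno)
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise ParseError(
                f"line {lineno}: gene_id and transcript_id attributes are mandatory"
            )
        tid = attrs["transcript_id"]
        iv = GenomicInterval(contig, start_i - 1, end_i, strand)
        if tid not in gene_of:
            gene_of[tid] = attrs["gene_id"]
            order.append(tid)
            attrs_of[tid] = {
                k: v for k, v in attrs.items() if k not in ("gene_id", "transcript_id")
            }
        if ftype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)
    models = []
    for tid in order:
        if tid not in exons:
            raise IntegrityError(f"transcript {tid} has CDS lines but no exons")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                exons=exons[tid],
                cds=cds.get(tid, []),
                attributes=attrs_of[tid],
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], source: str = "txforge") -> str:
    """Serialise transcript models to canonical GTF text."""
    out = ["##gff-version 2.2"]
    for m in models:
        for ftype, ivs in (("exon", m.exons), ("CDS", m.cds)):
            for iv in ivs:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                for k, v in m.attributes.items():
                    attrs += f' {k} "{v}";'
                out.append(
                    "\t".join(
                        (
                            iv.contig,
                            source,
                            ftype,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        )
                    )
                )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Transfrags (GTF with support/abundance attributes)


def read_transfrag_gtf(source, conditions: tuple[str, str] = ("PVS", "Egg")) -> list[Transfrag]:
    """Read assembled transfrags from GTF carrying support and abundance.

    The per-transfrag attributes are ``support`` (read pairs) and either
    ``abundance_<cond>`` keys or a Cufflinks-style ``FPKM`` (accepted as a
    single pooled abundance).
    """
    transfrags = []
    for m in read_gtf(source):
        support = int(float(m.attributes.pop("support", "0")))
        abundance: dict[str, float] = {}
        for cond in conditions:
            key = f"abundance_{cond}"
            if key in m.attributes:
                abundance[cond] = float(m.attributes.pop(key))
        if not abundance:
            for key in ("abundance", "FPKM"):
                if key in m.attributes:
                    val = float(m.attributes.pop(key))
                    abundance = {c: val for c in conditions}
                    break
        transfrags.append(Transfrag(model=m, support_pairs=support, abundance=abundance))
    return transfrags


def write_transfrag_gtf(transfrags: Iterable[Transfrag]) -> str:
    models = []
    for tf in transfrags:
        m = TranscriptModel(
            transcript_id=tf.model.transcript_id,
            gene_id=tf.model.gene_id,
            exons=list(tf.model.exons),
            cds=list(tf.model.cds),
            attributes=dict(tf.model.attributes),
        )
        m.attributes["support"] = str(tf.support_pairs)
        for cond, a in tf.abundance.items():
            m.attributes[f"abundance_{cond}"] = f"{a:g}"
        models.append(m)
    return write_gtf(models)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into an id -> uppercased sequence map.

    Ids are truncated at the first whitespace.  Duplicate ids raise an
    integrity error; characters outside {A,C,G,T,N} raise a parse error.
    """
    stream = _as_stream(source)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ParseError(
                f"sequence {rec.id}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        if rec.id in seqs:
            raise IntegrityError(f"duplicate FASTA id {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], width: int = 70) -> str:
    out = io.StringIO()
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    writer = SeqIO.FastaIO.FastaWriter(out, wrap=width)
    writer.write_file(records)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Repeat annotation (GFF3 dialect with class=/family= attributes)


def read_repeat_annotation(source) -> list[RepeatFeature]:
    stream = _as_stream(source)
    features = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
        contig, _src, _ftype, start, end, _score, strand, _phase, attr_field = fields
        attrs = {}
        for item in attr_field.split(";"):
            item = item.strip()
            if item and "=" in item:
                k, v = item.split("=", 1)
                attrs[k] = v
        if "class" not in attrs:
            raise ParseError(f"line {lineno}: repeat feature lacks class attribute")
        features.append(
            RepeatFeature(
                feature_id=attrs.get("ID", f"repeat_{lineno}"),
                interval=GenomicInterval(contig, int(start) - 1, int(end), strand),
                repeat_class=attrs["class"],
                family=attrs.get("family", ""),
            )
        )
    return features


def write_repeat_annotation(features: Iterable[RepeatFeature]) -> str:
    out = ["##gff-version 3"]
    for f in features:
        iv = f.interval
        out.append(
            "\t".join(
                (
                    iv.contig,
                    "txforge",
                    "repeat",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    f"ID={f.feature_id};class={f.repeat_class};family={f.family}",
                )
            )
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Alignments (simplified paired TSV: one row per genomic placement)

_ALN_COLUMNS = (
    "pair_id",
    "sample",
    "contig",
    "strand",
    "blocks",
    "n_hits",
    "both_ends_aligned",
    "same_contig_strand",
)


def read_alignments(source) -> list[ReadPairAlignment]:
    """Read placements from TSV; ``blocks`` is ``start-end;start-end`` (0-based)."""
    stream = _as_stream(source)
    alignments = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(_ALN_COLUMNS):
            raise ParseError(
                f"line {lineno}: expected {len(_ALN_COLUMNS)} fields, got {len(fields)}"
            )
        pair_id, sample, contig, strand, blocks_s, n_hits, bea, scs = fields
        blocks = []
        if blocks_s and blocks_s != ".":
            for span in blocks_s.split(";"):
                try:
                    s, e = span.split("-")
                    blocks.append(GenomicInterval(contig, int(s), int(e), strand))
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad block spec {span!r}") from exc
        alignments.append(
            ReadPairAlignment(
                pair_id=pair_id,
                sample=sample,
                blocks=blocks,
                n_hits=int(n_hits),
                both_ends_aligned=bea == "1",
                same_contig_strand=scs == "1",
            )
        )
    return alignments


def write_alignments(alignments: Iterable[ReadPairAlignment]) -> str:
    out = ["#" + "\t".join(_ALN_COLUMNS)]
    for a in alignments:
        blocks = ";".join(f"{b.start}-{b.end}" for b in a.blocks) or "."
        contig = a.blocks[0].contig if a.blocks else "."
        strand = a.blocks[0].strand if a.blocks else "."
        out.append(
            "\t".join(
                (
                    a.pair_id,
                    a.sample,
                    contig,
                    strand,
                    blocks,
                    str(a.n_hits),
                    "1" if a.both_ends_aligned else "0",
                    "1" if a.same_contig_strand else "0",
                )
            )
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Count tables


def read_counts(source) -> pd.DataFrame:
    """Read a TSV count table (rows = features, columns = samples)."""
    stream = _as_stream(source)
    df = pd.read_csv(stream, sep="\t", index_col=0, comment=None)
    df.index.name = "feature_id"
    return df


def write_counts(df: pd.DataFrame) -> str:
    out = io.StringIO()
    df.to_csv(out, sep="\t", index_label="#feature_id")
    return out.getvalue()
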