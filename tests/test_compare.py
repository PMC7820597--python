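"""Class-code classification, novel-gene calling and extension measurement."""

import numpy as np
import pandas as pd
import pytest

from txforge import compare, pipeline, synthetic
from txforge.model import GenomicInterval, Transfrag, TranscriptModel


def _model(tid, gid, spans, strand="+", contig="c"):
    return TranscriptModel(
        tid, gid, [GenomicInterval(contig, s, e, strand) for s, e in spans]
    )


def _tf(tid, spans, strand="+", contig="c", support=30, abundance=None):
    return Transfrag(
        model=_model(tid, f"loc_{tid}", spans, strand, contig),
        support_pairs=support,
        abundance=abundance or {"PVS": 100.0, "Egg": 100.0},
    )


REF = [
    _model("t1", "g1", [(100, 200), (300, 400), (500, 600)]),
    _model("t2", "g2", [(1000, 1200)], strand="-"),
]


def test_equal_code_survives_terminal_extension():
    """A transfrag matching the full intron chain is '=' even when its
    terminal exons grow past the reference boundaries."""
    tf = _tf("a", [(0, 200), (300, 400), (500, 900)])
    call = compare.classify_transfrag(tf, compare.ReferenceIndex(REF))
    assert call.code == "="
    assert call.matched_reference_transcript == "t1"


def test_j_code_for_shared_but_different_chain():
    tf = _tf("b", [(100, 200), (300, 340), (360, 400), (500, 600)])
    call = compare.classify_transfrag(tf, compare.ReferenceIndex(REF))
    assert call.code == "j"
    assert call.matched_locus == "g1"


def test_u_code_on_annotation_free_contig():
    tf = _tf("c1", [(50, 400)], contig="empty")
    assert compare.classify_transfrag(tf, compare.ReferenceIndex(REF)).code == "u"


def test_single_exon_inside_reference_is_not_u():
    tf = _tf("d", [(120, 180)])
    assert compare.classify_transfrag(tf, compare.ReferenceIndex(REF)).code == "other"


def test_antisense_overlap_is_other_not_u():
    tf = _tf("e", [(100, 200), (300, 400), (500, 600)], strand="-")
    assert compare.classify_transfrag(tf, compare.ReferenceIndex(REF)).code == "other"


def _oracle_code(tf, reference):
    """Exhaustive set-comparison of junction lists against every reference."""
    overlap = [
        r for r in reference
        if r.contig == tf.model.contig
        and any(
            e.start < re.end and re.start < e.end
            for e in tf.model.exons for re in r.exons
        )
    ]
    if not overlap:
        return "u"
    same = [r for r in overlap if r.strand == tf.model.strand]
    chain = tf.model.junctions
    for r in same:
        if chain == r.junctions and (chain or not r.is_multi_exon):
            return "="
    if len(tf.model.exons) > 1:
        for r in same:
            if set(chain) & set(r.junctions):
                return "j"
    return "other"


def test_classification_matches_exhaustive_oracle():
    """100 random transfrag/reference pairs agree with brute force."""
    rng = np.random.default_rng(11)

    def random_chain(start):
        spans, pos = [], start
        for _ in range(int(rng.integers(1, 5))):
            ln = int(rng.integers(50, 300))
            spans.append((pos, pos + ln))
            pos += ln + int(rng.integers(40, 200))
        return spans

    for trial in range(100):
        reference = []
        for r in range(int(rng.integers(1, 11))):
            strand = "+" if rng.random() < 0.5 else "-"
            reference.append(
                _model(f"r{r}", f"rg{r}", random_chain(int(rng.integers(0, 3000))),
                       strand)
            )
        mode = rng.random()
        base = reference[int(rng.integers(0, len(reference)))]
        spans = [(e.start, e.end) for e in base.exons]
        strand = base.strand
        if mode < 0.25 and len(spans) > 1:  # grow terminal exons, keep chain
            spans[0] = (max(0, spans[0][0] - 100), spans[0][1])
            spans[-1] = (spans[-1][0], spans[-1][1] + 150)
        elif mode < 0.5 and len(spans) > 2:  # drop one junction
            spans = spans[:-1]
        elif mode < 0.75:  # random chain elsewhere
            spans = random_chain(int(rng.integers(4000, 8000)))
            strand = "+" if rng.random() < 0.5 else "-"
        else:  # flip strand
            strand = "-" if strand == "+" else "+"
        tf = _tf(f"tf{trial}", spans, strand)
        got = compare.classify_transfrag(tf, compare.ReferenceIndex(reference))
        assert got.code == _oracle_code(tf, reference)


def test_novel_isoform_filters():
    calls = [
        compare.ClassCodeCall("j_ok", "j", "t1", "g1"),
        compare.ClassCodeCall("j_weak_support", "j", "t1", "g1"),
        compare.ClassCodeCall("j_low_fraction", "j", "t1", "g1"),
        compare.ClassCodeCall("j_low_cpm", "j", "t1", "g1"),
        compare.ClassCodeCall("major", "=", "t1", "g1"),
    ]
    tfs = [
        _tf("j_ok", [(100, 200)], abundance={"PVS": 50.0, "Egg": 0.0}),
        _tf("j_weak_support", [(100, 200)], support=19,
            abundance={"PVS": 50.0, "Egg": 0.0}),
        _tf("j_low_fraction", [(100, 200)], abundance={"PVS": 39.0, "Egg": 0.0}),
        _tf("j_low_cpm", [(100, 200)], abundance={"PVS": 50.0, "Egg": 0.0}),
        _tf("major", [(100, 200)], abundance={"PVS": 100.0, "Egg": 10.0}),
    ]
    cpm = {t.transfrag_id: {"PVS": 2.0, "Egg": 0.5} for t in tfs}
    cpm["j_low_cpm"] = {"PVS": 0.9, "Egg": 0.9}
    accepted = compare.accept_novel_isoforms(calls, tfs, cpm)
    assert accepted == {"j_ok"}


def test_isoform_fraction_monotonicity():
    calls = [compare.ClassCodeCall("major", "=", "t1", "g1")] + [
        compare.ClassCodeCall(f"j{i}", "j", "t1", "g1") for i in range(6)
    ]
    tfs = [_tf("major", [(0, 100)], abundance={"PVS": 100.0, "Egg": 100.0})] + [
        _tf(f"j{i}", [(0, 100)], abundance={"PVS": 100.0 - 12 * i, "Egg": 0.0})
        for i in range(6)
    ]
    cpm = {t.transfrag_id: {"PVS": 5.0, "Egg": 5.0} for t in tfs}
    sizes = [
        len(compare.accept_novel_isoforms(calls, tfs, cpm, min_isoform_fraction=f))
        for f in (0.2, 0.4, 0.6, 0.9)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_novel_gene_clustering_by_strand():
    calls = [
        compare.ClassCodeCall("u1", "u"),
        compare.ClassCodeCall("u2", "u"),
        compare.ClassCodeCall("u3", "u"),
    ]
    tfs = [
        _tf("u1", [(0, 500)], strand="+"),
        _tf("u2", [(300, 800)], strand="+"),
        _tf("u3", [(300, 800)], strand="-"),
    ]
    loci = compare.call_novel_genes(calls, tfs)
    assert len(loci) == 2
    sizes = sorted(len(l.members) for l in loci)
    assert sizes == [1, 2]


def test_support_threshold_monotone_in_novel_gene_count():
    rng = np.random.default_rng(3)
    calls, tfs = [], []
    for i in range(40):
        start = i * 1000
        calls.append(compare.ClassCodeCall(f"u{i}", "u"))
        tfs.append(_tf(f"u{i}", [(start, start + 400)],
                       support=int(rng.integers(0, 60))))
    counts = [len(compare.call_novel_genes(calls, tfs, min_support=s))
              for s in (0, 10, 20, 40)]
    assert counts == sorted(counts, reverse=True)


def test_extension_measurement_is_strand_aware():
    ref = [_model("t", "g", [(2000, 3000)], strand="-")]
    imp = [_model("t", "g", [(2000, 5000)], strand="-")]
    (rep,) = compare.measure_extensions(imp, ref)
    assert rep.five_prime_ext_bp == 2000
    assert rep.three_prime_ext_bp == 0
    assert rep.category == "5prime"


def test_identical_annotations_have_no_extension():
    reps = compare.measure_extensions(REF, REF)
    assert all(r.category == "none" for r in reps)


def test_expressed_gene_counting_thresholds():
    table = pd.DataFrame(
        {"PVS_1": [20, 39, 0], "PVS_2": [20, 0, 0], "Egg_1": [0, 1, 0],
         "Egg_2": [0, 0, 0]},
        index=["g40", "g39", "g0"],
    )
    cond = {"PVS_1": "PVS", "PVS_2": "PVS", "Egg_1": "Egg", "Egg_2": "Egg"}
    out = compare.count_expressed_genes(table, cond, threshold=40)
    assert out["PVS"] == {"g40"}
    out10 = compare.count_expressed_genes(table, cond, threshold=10)
    assert out10["PVS"] == {"g40", "g39"}
    assert compare.count_expressed_genes(table.iloc[:0], cond)["PVS"] == set()


def test_ledger_recovery_of_novel_loci_and_extensions(dataset):
    """Dropped genes come back as novel loci; truncations as extensions."""
    ledger = dataset["ledger"]
    calls = compare.classify_all(dataset["transfrags"], dataset["reference"])
    loci = compare.call_novel_genes(calls, dataset["transfrags"])
    expressed_dropped = (
        synthetic.expressed_gene_ids(dataset["transfrags"]) & ledger.dropped_genes
    )
    truth_spans = {}
    for m in dataset["truth"]:
        if m.gene_id in expressed_dropped:
            s, e = truth_spans.get(m.gene_id, (m.start, m.end))
            truth_spans[m.gene_id] = (min(s, m.start), max(e, m.end))
    locus_spans = {(l.span.contig, l.span.start, l.span.end) for l in loci}
    expected = set()
    for gid, (s, e) in truth_spans.items():
        contig = next(m.contig for m in dataset["truth"] if m.gene_id == gid)
        expected.add((contig, s, e))
    assert locus_spans == expected

    cpm = pipeline._transfrag_cpm(dataset["transfrags"])
    accepted = compare.accept_novel_isoforms(calls, dataset["transfrags"], cpm)
    improved = compare.build_improved_annotation(
        dataset["reference"], dataset["transfrags"], calls, accepted)
    ext = {
        r.gene_id: (r.five_prime_ext_bp, r.three_prime_ext_bp)
        for r in compare.measure_extensions(improved, dataset["reference"])
        if r.category != "none"
    }
    assert ext == ledger.truncations
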