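"""Counting rules, CPM/TPM, TMM, the NB Wald test and enrichment."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txforge import quantde
from txforge.model import GenomicInterval, ReadPairAlignment, TranscriptModel

COND = {"PVS_1": "PVS", "PVS_2": "PVS", "Egg_1": "Egg", "Egg_2": "Egg"}
COLS = ["PVS_1", "PVS_2", "Egg_1", "Egg_2"]


def _nb(rng, mu, alpha, size):
    n = 1 / alpha
    return rng.negative_binomial(n, n / (n + mu), size=size)


def _gene(gid, start, end, contig="c"):
    return TranscriptModel(f"{gid}.t", gid,
                           [GenomicInterval(contig, start, end, "+")])


def _pair(pid, spans, contig="c", n_hits=1, sample="PVS_1", **kw):
    return ReadPairAlignment(
        pair_id=pid, sample=sample,
        blocks=[GenomicInterval(contig, s, e, "+") for s, e in spans],
        n_hits=n_hits, **kw,
    )


class TestCounting:
    def test_largest_overlap_wins(self):
        genes = [_gene("A", 0, 1000), _gene("B", 960, 2000)]
        pair = _pair("p", [(900, 980), (980, 1000)])  # 80 bp in A beyond B's start
        cm = quantde.count_gene_pairs([pair], genes, condition_of=COND)
        assert cm.counts.loc["A", "PVS_1"] == 1
        assert cm.counts.loc["B", "PVS_1"] == 0

    def test_flag_filters_exclude_pairs(self):
        genes = [_gene("A", 0, 1000)]
        bad1 = _pair("p1", [(10, 100)], same_contig_strand=False)
        bad2 = ReadPairAlignment("p2", "PVS_1", [], n_hits=1,
                                 both_ends_aligned=False)
        cm = quantde.count_gene_pairs([bad1, bad2], genes, condition_of=COND)
        assert cm.counts.values.sum() == 0

    def test_unique_only_drops_multimappers(self):
        genes = [_gene("A", 0, 1000)]
        multi = _pair("p", [(10, 100)], n_hits=3)
        cm = quantde.count_gene_pairs([multi], genes, "unique_only", COND)
        assert cm.counts.values.sum() == 0
        cm2 = quantde.count_gene_pairs([multi], genes, "fractional", COND)
        assert cm2.counts.loc["A", "PVS_1"] == pytest.approx(1 / 3)

    def test_exact_tie_counts_both_genes(self):
        genes = [_gene("A", 0, 1000), _gene("B", 1000, 2000)]
        pair = _pair("p", [(950, 1000), (1000, 1050)])
        cm = quantde.count_gene_pairs([pair], genes, condition_of=COND)
        assert cm.counts.loc["A", "PVS_1"] == 1 and cm.counts.loc["B", "PVS_1"] == 1
        cm_strict = quantde.count_gene_pairs([pair], genes, condition_of=COND,
                                             largest_overlap_ties="first")
        assert cm_strict.counts.values.sum() == 1


class TestScaling:
    def test_cpm_identity(self):
        counts = pd.DataFrame({"s": [50]}, index=["g"])
        assert quantde.cpm(counts, {"s": 1e6}).loc["g", "s"] == 50

    def test_tpm_uniform_case_and_sum(self):
        counts = pd.DataFrame({"s": [10, 10, 10, 10]}, index=list("abcd"))
        t = quantde.tpm(counts, {g: 100.0 for g in "abcd"})
        assert (t["s"] == 250_000).all()
        rng = np.random.default_rng(0)
        counts2 = pd.DataFrame({"s": rng.integers(1, 500, 30)},
                               index=[f"g{i}" for i in range(30)])
        t2 = quantde.tpm(counts2, {f"g{i}": float(rng.integers(200, 3000))
                                   for i in range(30)})
        assert t2["s"].sum() == pytest.approx(1e6)

    def test_low_expression_filter_is_strict(self):
        cpm_table = pd.DataFrame(
            [[1.5, 1.2, 0, 0], [1.0, 1.0, 1.0, 1.0], [5, 0, 0, 0]],
            columns=COLS, index=["keep", "boundary", "single"],
        )
        assert quantde.filter_low_expression(cpm_table) == ["keep"]
        assert quantde.filter_low_expression(cpm_table.iloc[:0]) == []


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = _nb(rng, 200, 0.1, 300)
        counts = pd.DataFrame({"a": col, "b": col})
        f = quantde.tmm_factors(counts)
        assert f["a"] == pytest.approx(1.0) and f["b"] == pytest.approx(1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        col = _nb(rng, 300, 0.05, 400)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = quantde.tmm_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(1.0, abs=1e-9)

    @staticmethod
    def _oracle_tmm(counts: pd.DataFrame) -> dict:
        """Step-by-step trimmed-mean evaluation, written independently of
        the implementation (pandas ranking, explicit boolean trims)."""
        lib = counts.sum(axis=0).astype(float)
        uq = (counts / lib * 1e6).quantile(0.75)
        ref_name = (uq - uq.mean()).abs().idxmin()
        ref, n_ref = counts[ref_name].to_numpy(float), float(lib[ref_name])
        out = {}
        for s in counts.columns:
            obs, n_obs = counts[s].to_numpy(float), float(lib[s])
            ok = (obs > 0) & (ref > 0)
            o, r = obs[ok], ref[ok]
            m = np.log2((o / n_obs) / (r / n_ref))
            a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
            w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
            if np.max(np.abs(m)) < 1e-6:
                out[s] = 1.0
                continue
            n = len(m)
            # trim by average rank (ties share a rank, as in the method's
            # reference implementation); bounds are inclusive
            rm = pd.Series(m).rank().to_numpy()
            ra = pd.Series(a).rank().to_numpy()
            lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
            lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
            sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
            out[s] = 2.0 ** (np.sum(m[sel] * w[sel]) / np.sum(w[sel]))
        gm = np.exp(np.mean(np.log(list(out.values()))))
        return {s: v / gm for s, v in out.items()}

    def test_factors_match_independent_evaluation(self):
        rng = np.random.default_rng(7)
        mus = np.exp(rng.normal(5, 1, 500))
        counts = pd.DataFrame(
            {s: _nb(rng, mus * (1 + 0.3 * i), 0.05, 500)
             for i, s in enumerate(COLS)},
            index=[f"g{i}" for i in range(500)],
        )
        got = quantde.tmm_factors(counts)
        expect = self._oracle_tmm(counts)
        for s in COLS:
            assert got[s] == pytest.approx(expect[s], abs=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_factors_match_edger(self, tmp_path):
        """Cross-check against the reference TMM implementation in edgeR."""
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            _nb(rng, np.exp(rng.normal(5, 1, (400, 4))), 0.1, None),
            columns=COLS, index=[f"g{i}" for i in range(400)],
        )
        csv = tmp_path / "c.csv"
        counts.to_csv(csv)
        script = (
            'suppressMessages(library(edgeR)); '
            f'x <- read.csv("{csv}", row.names=1); '
            'cat(calcNormFactors(as.matrix(x), method="TMM"), sep="\\n")'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        expect = dict(zip(COLS, map(float, res.stdout.split())))
        got = quantde.tmm_factors(counts)
        for s in COLS:
            assert got[s] == pytest.approx(expect[s], abs=1e-6)


class TestWald:
    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(_nb(rng, 500, 0.05, (2000, 4)), columns=COLS,
                              index=[f"g{i}" for i in range(2000)])
        cm = quantde.CountMatrix(counts, COND, {s: 1e6 for s in COLS})
        res = quantde.nb_wald_test(cm, {s: 1.0 for s in COLS})
        p = np.array([r.p_value for r in res])
        assert 0.03 <= (p < 0.05).mean() <= 0.08

    def test_power_on_planted_fold_change(self):
        rng = np.random.default_rng(43)
        mus = [500, 500, 4000, 4000]  # log2fc = 3 in Egg
        counts = pd.DataFrame(np.column_stack([_nb(rng, m, 0.05, 500) for m in mus]),
                              columns=COLS, index=[f"g{i}" for i in range(500)])
        cm = quantde.CountMatrix(counts, COND, {s: 1e6 for s in COLS})
        res = quantde.classify_degs(quantde.nb_wald_test(cm, {s: 1.0 for s in COLS}))
        assert np.mean([r.label == "up" for r in res]) >= 0.9

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(44)
        counts = pd.DataFrame(_nb(rng, np.exp(rng.normal(5, 1, (100, 4))), 0.1, None),
                              columns=COLS, index=[f"g{i}" for i in range(100)])
        cm = quantde.CountMatrix(counts, COND, {s: 1e6 for s in COLS})
        fwd = quantde.nb_wald_test(cm, {s: 1.0 for s in COLS})
        rev = quantde.nb_wald_test(cm, {s: 1.0 for s in COLS},
                                   conditions=("Egg", "PVS"))
        np.testing.assert_allclose([r.log2fc for r in fwd],
                                   [-r.log2fc for r in rev], atol=1e-6)

    def test_design_with_single_replicate_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], columns=["PVS_1", "PVS_2", "Egg_1"],
                              index=["g"])
        cm = quantde.CountMatrix(counts, COND, {s: 1e6 for s in counts.columns})
        with pytest.raises(Exception):
            quantde.nb_wald_test(cm, {s: 1.0 for s in counts.columns})

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(45)
        counts = pd.DataFrame(_nb(rng, 300, 0.2, (300, 4)), columns=COLS,
                              index=[f"g{i}" for i in range(300)])
        cm = quantde.CountMatrix(counts, COND, {s: 1e6 for s in COLS})
        res = quantde.nb_wald_test(cm, {s: 1.0 for s in COLS})
        df = pd.DataFrame({"p": [r.p_value for r in res],
                           "q": [r.padj for r in res]}).sort_values("p")
        assert (df["q"] >= df["p"] - 1e-12).all()
        assert (df["q"].diff().dropna() >= -1e-12).all()
        assert (df["q"] <= 1.0).all()
        # agrees with the statsmodels implementation
        from statsmodels.stats.multitest import multipletests

        expect = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(df["q"].to_numpy(), expect, atol=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "padj,fc,label",
        [(0.005, 3.0, "up"), (0.005, 2.0, "ns"), (0.02, 10.0, "ns"),
         (0.005, 1 / 3.0, "down"), (0.01, 2.5, "up")],
    )
    def test_deg_thresholds(self, padj, fc, label):
        r = quantde.DEResult("g", 100.0, math.log2(fc), 1e-4, padj=padj)
        quantde.classify_degs([r])
        assert r.label == label

    def test_top_k_ordering_and_exclusion(self):
        res = [
            quantde.DEResult("hi", 0, 2.0, 1e-9, 1e-8, "up"),
            quantde.DEResult("lo", 0, 2.0, 1e-9, 1e-8, "up"),
            quantde.DEResult("ribo", 0, 2.0, 1e-9, 1e-8, "up"),
        ]
        cpm_table = pd.DataFrame(
            {"Egg_1": [100, 50, 500], "Egg_2": [100, 50, 500],
             "PVS_1": [1, 1, 1], "PVS_2": [1, 1, 1]},
            index=["hi", "lo", "ribo"],
        )
        top = quantde.top_k_table(res, cpm_table, COND, "up", k=25,
                                  exclude={"ribo"})
        assert list(top.index) == ["hi", "lo"]
        top2 = quantde.top_k_table(res, cpm_table, COND, "up", k=1)
        assert list(top2.index) == ["ribo"]
        with pytest.raises(ValueError):
            quantde.top_k_table(res, cpm_table, COND, "up", k=0)


class TestEnrichment:
    def test_perfect_overlap_extreme_case(self):
        background = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(10)}
        df = quantde.hypergeom_enrichment(term, background, {"T": term})
        assert len(df) == 1
        expected_p = 1.0 / math.comb(1000, 10)
        assert df.loc["T", "p_value"] == pytest.approx(expected_p, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        background = {f"g{i}" for i in range(100)}
        p = float(stats.hypergeom.sf(-1, 100, 10, 5))
        assert p == 1.0
        df = quantde.hypergeom_enrichment(
            {"g50"}, background, {"T": {f"g{i}" for i in range(10)}}, fdr=1.1)
        assert df.empty  # overlap 0 terms are never reported

    def test_selected_outside_background_rejected(self):
        with pytest.raises(Exception):
            quantde.hypergeom_enrichment({"x"}, {"a"}, {"T": {"a"}})

    def test_null_selection_controls_fdr(self):
        rng = np.random.default_rng(46)
        background = {f"g{i}" for i in range(400)}
        term_map = {
            f"T{k}": set(rng.choice(sorted(background), size=25, replace=False))
            for k in range(40)
        }
        hits = []
        for _ in range(30):
            selected = set(rng.choice(sorted(background), size=40, replace=False))
            df = quantde.hypergeom_enrichment(selected, background, term_map)
            hits.append(len(df) / len(term_map))
        assert np.mean(hits) <= 0.05
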