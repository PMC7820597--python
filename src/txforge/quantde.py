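"""Gene-level counting, normalization and negative-binomial differential
expression for the two-stage (PVS vs Egg), two-replicate design.

Counting follows paired-fragment rules: pairs must have both ends aligned
on the same contig and strand; a pair overlapping several genes goes to the
gene with the largest overlapped base count, with exact ties counted once
for every tied gene.  Between-sample scaling uses the trimmed mean of
M-values (TMM): log-ratios trimmed 30%, log-abundances trimmed 5%,
precision-weighted by the inverse binomial variance approximation, factors
rescaled to geometric mean one.  The DE engine is a negative-binomial Wald
test: per-gene dispersion alpha (variance mu + alpha mu^2) by method of
moments on normalized counts with a small floor, coefficients by IRLS, and
Benjamini-Hochberg adjustment across tested genes.  A gene is called
differentially expressed at padj <= 0.01 and linear fold change (Egg/PVS)
>= 2.5 or <= 1/2.5; "up" means higher in Egg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ComputationError, DesignError, IntegrityError
from .model import ReadPairAlignment, TranscriptModel


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # genes x samples, float (fractional) or int
    condition_of: dict[str, str]  # sample -> condition
    library_size: dict[str, float]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise IntegrityError("negative counts")


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p_value: float
    padj: float = float("nan")
    label: str = "ns"


# ---------------------------------------------------------------------------
# Counting


def count_gene_pairs(
    alignments: list[ReadPairAlignment],
    annotation: list[TranscriptModel],
    multi_policy: str = "unique_only",
    condition_of: dict[str, str] | None = None,
    largest_overlap_ties: str = "all",
) -> CountMatrix:
    """Count read pairs per gene under paired-fragment filtering rules.

    ``multi_policy``: ``unique_only`` counts only pairs with a single
    genomic placement; ``fractional`` weights each placement 1/n_hits.
    ``largest_overlap_ties``: ``all`` counts an exactly-tied pair once for
    each tied gene; ``first`` counts it for the lexicographically first.
    """
    trees: dict[str, IntervalTree] = {}
    gene_ids: set[str] = set()
    for m in annotation:
        gene_ids.add(m.gene_id)
        tree = trees.setdefault(m.contig, IntervalTree())
        for e in m.exons:
            tree.addi(e.start, e.end, m.gene_id)

    pairs: dict[tuple[str, str], list[ReadPairAlignment]] = {}
    samples: list[str] = []
    for a in alignments:
        if a.sample not in samples:
            samples.append(a.sample)
        pairs.setdefault((a.sample, a.pair_id), []).append(a)

    counts: dict[str, dict[str, float]] = {g: {} for g in sorted(gene_ids)}
    library_size: dict[str, float] = {s: 0.0 for s in samples}
    for (sample, _pid), placements in pairs.items():
        if not all(p.both_ends_aligned and p.same_contig_strand for p in placements):
            continue
        n_hits = placements[0].n_hits
        if multi_policy == "unique_only" and n_hits > 1:
            continue
        library_size[sample] += 1.0
        weight = 1.0 if multi_policy == "unique_only" else 1.0 / n_hits
        for pl in placements:
            overlap_bp: dict[str, int] = {}
            for b in pl.blocks:
                tree = trees.get(b.contig)
                if tree is None:
                    continue
                for iv in tree.overlap(b.start, b.end):
                    shared = min(b.end, iv.end) - max(b.start, iv.begin)
                    overlap_bp[iv.data] = overlap_bp.get(iv.data, 0) + shared
            if not overlap_bp:
                continue
            best = max(overlap_bp.values())
            winners = sorted(g for g, bp in overlap_bp.items() if bp == best)
            if largest_overlap_ties == "first":
                winners = winners[:1]
            for g in winners:
                counts[g][sample] = counts[g].get(sample, 0.0) + weight
    df = pd.DataFrame(
        [[counts[g].get(s, 0.0) for s in samples] for g in sorted(gene_ids)],
        index=sorted(gene_ids),
        columns=samples,
    )
    return CountMatrix(
        counts=df,
        condition_of=condition_of or {},
        library_size=library_size,
    )


# ---------------------------------------------------------------------------
# CPM / TPM


def cpm(counts: pd.DataFrame, library_size: dict[str, float] | None = None) -> pd.DataFrame:
    """Counts per million; the denominator defaults to per-sample assigned totals."""
    if library_size is None:
        lib = counts.sum(axis=0)
    else:
        lib = pd.Series({s: library_size[s] for s in counts.columns})
    if (lib <= 0).any():
        raise ComputationError("zero library size")
    return counts / lib * 1e6


def tpm(counts: pd.DataFrame, lengths: dict[str, float]) -> pd.DataFrame:
    """Transcripts per million given feature lengths in bp."""
    lens = pd.Series({g: lengths[g] for g in counts.index})
    if (lens <= 0).any():
        raise ComputationError("non-positive feature length")
    rate = counts.div(lens, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ComputationError("zero total rate in TPM")
    return rate / denom * 1e6


def filter_low_expression(
    cpm_table: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> list[str]:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples."""
    keep = (cpm_table > min_cpm).sum(axis=1) >= min_samples
    return list(cpm_table.index[keep])


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Scaling factor of one sample against the reference (log2 result 2^f)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    m_rank = stats.rankdata(m)
    a_rank = stats.rankdata(a)
    keep2 = (m_rank >= lo_l) & (m_rank <= hi_l) & (a_rank >= lo_s) & (a_rank <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None) -> dict[str, float]:
    """Per-sample TMM scaling factors, rescaled to geometric mean one.

    The automatic reference is the sample whose upper quartile of CPM is
    closest to the mean upper quartile.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ComputationError("a sample has all-zero counts")
    if reference_sample is None:
        uq = (counts / lib * 1e6).quantile(0.75, axis=0)
        reference_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[reference_sample].to_numpy()
    n_ref = float(lib[reference_sample])
    factors = {}
    for s in counts.columns:
        factors[s] = _tmm_pair(counts[s].to_numpy(), ref, float(lib[s]), n_ref)
    log_gm = np.mean([math.log(f) for f in factors.values()])
    return {s: f / math.exp(log_gm) for s, f in factors.items()}


# ---------------------------------------------------------------------------
# NB Wald test


def _estimate_dispersion(
    z: np.ndarray, groups: np.ndarray, size: np.ndarray, floor: float = 1e-8
) -> float:
    """Method-of-moments dispersion on normalized counts, pooled over groups.

    For normalized counts z = y/s with y ~ NB(s*mu, alpha):
    Var(z) = mu/s + alpha*mu^2, so the shot-noise term uses the per-group
    mean of 1/s.
    """
    resid_sq, shot_terms, denom = 0.0, 0.0, 0.0
    for g in np.unique(groups):
        sel = groups == g
        zg, sg = z[sel], size[sel]
        if zg.size < 2:
            continue
        m = zg.mean()
        resid_sq += np.sum((zg - m) ** 2)
        shot_terms += (zg.size - 1) * m * np.mean(1.0 / sg)
        denom += (zg.size - 1) * m * m
    if denom <= 0:
        return floor
    alpha = (resid_sq - shot_terms) / denom
    return max(alpha, floor)


def _nb_irls(y: np.ndarray, offset: np.ndarray, x: np.ndarray, alpha: float,
             max_iter: int = 50, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Fit log-link NB regression with known dispersion; returns (beta, cov)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    mean_y = max(np.mean(y / np.exp(offset)), 1e-8)
    beta[0] = math.log(mean_y)
    for _ in range(max_iter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtwx = X.T @ (w[:, None] * X)
        xtwz = X.T @ (w * z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    cov = np.linalg.pinv(X.T @ (w[:, None] * X))
    return beta, cov


def nb_wald_test(
    count_matrix: CountMatrix,
    factors: dict[str, float],
    conditions: tuple[str, str] = ("PVS", "Egg"),
    dispersion: str = "common",
) -> list[DEResult]:
    """Two-group negative-binomial Wald test (second condition vs first).

    Size factors are library size x TMM factor, scaled to geometric mean
    one; log2fc is oriented so positive means higher in the second
    condition (Egg).  ``dispersion='common'`` (default) pools the per-gene
    method-of-moments estimates into one shared alpha — with two replicates
    per group a per-gene estimate is far too noisy to keep the Wald test
    calibrated; ``'per_gene'`` uses the raw per-gene estimates.
    """
    cond_of = count_matrix.condition_of
    samples = list(count_matrix.counts.columns)
    group = np.array([1.0 if cond_of[s] == conditions[1] else 0.0 for s in samples])
    for g_val in (0.0, 1.0):
        if (group == g_val).sum() < 2:
            raise DesignError("each group needs at least two replicates")
    size = np.array(
        [count_matrix.library_size.get(s, count_matrix.counts[s].sum()) * factors[s]
         for s in samples]
    )
    size = size / math.exp(np.mean(np.log(size)))
    offset = np.log(size)
    mat = count_matrix.counts
    gene_alphas: dict[str, float] = {}
    for gene_id, row in mat.iterrows():
        y = row.to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        gene_alphas[gene_id] = _estimate_dispersion(y / size, group, size)
    if not gene_alphas:
        return []
    common_alpha = max(float(np.mean(list(gene_alphas.values()))), 1e-8)
    results = []
    for gene_id, row in mat.iterrows():
        if gene_id not in gene_alphas:
            continue
        y = row.to_numpy(dtype=float)
        z = y / size
        alpha = common_alpha if dispersion == "common" else gene_alphas[gene_id]
        beta, cov = _nb_irls(y, offset, group, alpha)
        se = math.sqrt(max(cov[1, 1], 1e-300))
        wald = beta[1] / se
        p = 2.0 * stats.norm.sf(abs(wald))
        results.append(
            DEResult(
                gene_id=gene_id,
                base_mean=float(z.mean()),
                log2fc=float(beta[1] / math.log(2.0)),
                p_value=float(min(max(p, 0.0), 1.0)),
            )
        )
    _bh_adjust(results)
    return results


def _bh_adjust(results: list[DEResult]) -> None:
    if not results:
        return
    p = np.array([r.p_value for r in results])
    order = np.argsort(p)
    n = p.size
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    for r, q in zip(results, adj):
        r.padj = float(q)


def classify_degs(
    results: list[DEResult],
    fc_threshold: float = 2.5,
    padj_threshold: float = 0.01,
    fc_scale: str = "linear",
) -> list[DEResult]:
    """Label results up/down/ns at the padj and fold-change thresholds.

    ``fc_scale='linear'`` (default) reads the threshold as a linear fold
    change (up: 2^log2fc >= 2.5); ``'log2'`` applies it to log2fc directly.
    """
    for r in results:
        if fc_scale == "linear":
            fc = 2.0 ** r.log2fc
            up = fc >= fc_threshold
            down = fc <= 1.0 / fc_threshold
        else:
            up = r.log2fc >= fc_threshold
            down = r.log2fc <= -fc_threshold
        if r.padj <= padj_threshold and up:
            r.label = "up"
        elif r.padj <= padj_threshold and down:
            r.label = "down"
        else:
            r.label = "ns"
    return results


def top_k_table(
    results: list[DEResult],
    cpm_table: pd.DataFrame,
    condition_of: dict[str, str],
    direction: str,
    k: int = 25,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Top-k DEGs of one direction ranked by mean CPM in that condition.

    ``direction`` 'up' ranks by mean Egg CPM, 'down' by mean PVS CPM; genes
    in ``exclude`` (e.g. ribosomal-protein genes) are removed first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exclude = exclude or set()
    condition = "Egg" if direction == "up" else "PVS"
    samples = [s for s in cpm_table.columns if condition_of[s] == condition]
    rows = []
    for r in results:
        if r.label != direction or r.gene_id in exclude:
            continue
        if r.gene_id not in cpm_table.index:
            continue
        mean_cpm = float(cpm_table.loc[r.gene_id, samples].mean())
        rows.append((r.gene_id, mean_cpm, r.log2fc, r.padj))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(
        rows[:k], columns=["gene_id", "mean_cpm", "log2fc", "padj"]
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Enrichment


def hypergeom_enrichment(
    selected: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test with BH control.

    For each term with at least one selected gene, the upper-tail
    probability of the observed overlap given the background is computed;
    terms at BH FDR <= ``fdr`` are returned with their enrichment ratio
    (overlap/|selected|) / (term size/|background|).
    """
    missing = selected - background
    if missing:
        raise IntegrityError(f"selected genes absent from background: {sorted(missing)[:5]}")
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for term, genes in sorted(term_map.items()):
        term_bg = genes & background
        overlap = len(term_bg & selected)
        if overlap == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(term_bg), n_sel))
        ratio = (overlap / n_sel) / (len(term_bg) / n_bg) if term_bg else float("nan")
        rows.append((term, overlap, len(term_bg), p, ratio))
    if not rows:
        return pd.DataFrame(
            columns=["term", "overlap", "term_size", "p_value", "padj", "enrichment"]
        ).set_index("term")
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value", "enrichment"])
    p = df["p_value"].to_numpy()
    order = np.argsort(p)
    adj = np.empty(p.size)
    running = 1.0
    for rank_idx in range(p.size - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * p.size / (rank_idx + 1))
        adj[i] = running
    df["padj"] = adj
    df = df[df["padj"] <= fdr].sort_values("p_value")
    return df.set_index("term")[["overlap", "term_size", "p_value", "padj", "enrichment"]]
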