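"""End-to-end orchestration of the annotation-improvement pipeline.

``run_pipeline`` drives the stages in their fixed order — simulate ->
compare -> orfs -> rescue -> repeats -> de -> enrich — with every
threshold taken from one config mapping, and writes a machine-readable
run report whose counts equal the records in the emitted files.  Reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

from . import compare, io_formats, orfs, quantde, repeats, rescue, synthetic
from .errors import ConfigError
from .synthetic import CONDITION_OF, SAMPLES, SimulationConfig

log = logging.getLogger("txforge")

#: every tunable threshold with its default
DEFAULT_THRESHOLDS = {
    "min_support": 20,
    "expressed_cutoff": 40,
    "min_isoform_fraction": 0.4,
    "min_cpm": 1.0,
    "min_cpm_samples": 2,
    "stage_tpm_min": 10.0,
    "cluster_identity": 0.95,
    "final_reads_min": 20.0,
    "min_aa": 100,
    "min_region_bp": 500,
    "fc_threshold": 2.5,
    "padj_threshold": 0.01,
    "enrichment_fdr": 0.05,
}


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def resolve_config(cfg: dict | None = None) -> dict:
    cfg = dict(cfg or {})
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    sim_kwargs = cfg.get("simulate", {})
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    bad = set(sim_kwargs) - known
    if bad:
        raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
    return {"thresholds": thresholds, "simulate": sim_kwargs,
            "seed": int(cfg.get("seed", 0))}


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run all stages on a simulated dataset; return the run report.

    ``config`` is the (possibly partial) config mapping; ``outdir``, when
    given, receives the GTF/TSV/JSON outputs alongside ``report.json``.
    """
    resolved = resolve_config(config)
    th = resolved["thresholds"]
    sim_cfg = SimulationConfig(seed=resolved["seed"], **resolved["simulate"])
    report: dict = {"config": {**resolved, "simulate_resolved": _cfg_dict(sim_cfg)},
                    "stages": {}, "seed": resolved["seed"]}
    t0 = time.time()

    def stage(name):
        log.info("stage %s starting (thresholds: %s)", name, th)
        return time.time()

    # --- simulate
    t = stage("simulate")
    genome = synthetic.generate_genome(sim_cfg)
    truth, reference, ledger = synthetic.generate_annotation_pair(genome, sim_cfg)
    counts = synthetic.simulate_counts(truth, sim_cfg, ledger)
    transfrags = synthetic.simulate_transfrags(truth, counts, sim_cfg)
    rep_features, rep_alignments = synthetic.simulate_repeat_landscape(
        genome, sim_cfg, ledger)
    pool = synthetic.simulate_unmapped_pool(truth, genome, ledger, sim_cfg)
    contigs = synthetic.simulate_denovo_contigs(truth, genome, ledger, counts, sim_cfg)
    report["stages"]["simulate"] = {
        "truth_transcripts": len(truth),
        "reference_transcripts": len(reference),
        "dropped_genes": len(ledger.dropped_genes),
        "transfrags": len(transfrags),
        "repeat_copies": len(rep_features),
        "unmapped_reads": len(pool),
        "seconds": round(time.time() - t, 3),
    }

    # --- compare
    t = stage("compare")
    calls = compare.classify_all(transfrags, reference)
    tf_cpm = _transfrag_cpm(transfrags)
    accepted = compare.accept_novel_isoforms(
        calls, transfrags, tf_cpm,
        min_support=th["min_support"],
        min_isoform_fraction=th["min_isoform_fraction"],
        min_cpm=th["min_cpm"],
    )
    loci = compare.call_novel_genes(calls, transfrags, min_support=th["min_support"])
    improved = compare.build_improved_annotation(reference, transfrags, calls, accepted)
    extensions = compare.measure_extensions(improved, reference)
    ext_counts = {"5prime": 0, "3prime": 0, "both": 0, "none": 0}
    for e in extensions:
        ext_counts[e.category] += 1
    report["stages"]["compare"] = {
        "class_codes": _tally(c.code for c in calls),
        "novel_loci": len(loci),
        "accepted_isoforms": len(accepted),
        "extensions": ext_counts,
        "seconds": round(time.time() - t, 3),
    }

    # --- orfs
    t = stage("orfs")
    improvement = orfs.cds_improvement_report(reference, improved, genome,
                                              min_aa=th["min_aa"])
    cat_tally: dict[str, int] = {}
    for cats in improvement.values():
        for c in cats:
            cat_tally[c] = cat_tally.get(c, 0) + 1
    report["stages"]["orfs"] = {
        "categories": cat_tally,
        "seconds": round(time.time() - t, 3),
    }

    # --- rescue
    t = stage("rescue")
    retained_reads = rescue.rescue_filter_reads(pool)
    survivors, clusters = rescue.rescue_cascade(
        contigs,
        stage_tpm_min=th["stage_tpm_min"],
        cluster_identity=th["cluster_identity"],
        final_reads_min=th["final_reads_min"],
        min_aa=th["min_aa"],
    )
    report["stages"]["rescue"] = {
        "reads_in": len(pool),
        "reads_retained": len(retained_reads),
        "contigs_in": len(contigs),
        "contigs_retained": len(survivors),
        "clusters": len(clusters),
        "coding_retained": sum(1 for c in survivors if c.coding),
        "seconds": round(time.time() - t, 3),
    }

    # --- repeats
    t = stage("repeats")
    regions = repeats.filter_regions_by_length(
        repeats.merge_repeat_features(rep_features), th["min_region_bp"])
    assignment = repeats.assign_pairs_fractional(rep_alignments, improved, regions)
    report["stages"]["repeats"] = {
        "merged_regions": len(regions),
        "class_weights": {
            cls: round(s.total, 3)
            for cls, s in sorted(assignment.class_summaries.items())
        },
        "ambiguous": round(sum(assignment.ambiguous_weight.values()), 3),
        "total_pairs": sum(assignment.total_pairs.values()),
        "seconds": round(time.time() - t, 3),
    }

    # --- de
    t = stage("de")
    gene_counts = _gene_level(counts, truth)
    cm = quantde.CountMatrix(
        counts=gene_counts,
        condition_of=dict(CONDITION_OF),
        library_size={s: float(gene_counts[s].sum()) for s in gene_counts.columns},
    )
    cpm_table = quantde.cpm(cm.counts, cm.library_size)
    kept = quantde.filter_low_expression(cpm_table, th["min_cpm"], th["min_cpm_samples"])
    sub = quantde.CountMatrix(cm.counts.loc[kept], cm.condition_of, cm.library_size)
    factors = quantde.tmm_factors(sub.counts)
    results = quantde.nb_wald_test(sub, factors)
    results = quantde.classify_degs(results, th["fc_threshold"], th["padj_threshold"])
    n_up = sum(1 for r in results if r.label == "up")
    n_down = sum(1 for r in results if r.label == "down")
    expressed = compare.count_expressed_genes(
        gene_counts, dict(CONDITION_OF), th["expressed_cutoff"])
    report["stages"]["de"] = {
        "genes_tested": len(results),
        "deg_up": n_up,
        "deg_down": n_down,
        "expressed_genes": {c: len(g) for c, g in expressed.items()},
        "tmm_factors": {s: round(f, 4) for s, f in factors.items()},
        "seconds": round(time.time() - t, 3),
    }

    # --- enrich (planted-DE genes as the term map: a self-test of recovery)
    t = stage("enrich")
    selected = {r.gene_id for r in results if r.label != "ns"}
    background = set(gene_counts.index)
    term_map = {"planted_de": set(ledger.planted_de) & background}
    enriched = quantde.hypergeom_enrichment(
        selected & background, background, term_map, fdr=th["enrichment_fdr"])
    report["stages"]["enrich"] = {
        "terms_enriched": int(len(enriched)),
        "seconds": round(time.time() - t, 3),
    }

    report["total_seconds"] = round(time.time() - t0, 3)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth.gtf").write_text(io_formats.write_gtf(truth))
        (outdir / "reference.gtf").write_text(io_formats.write_gtf(reference))
        (outdir / "improved.gtf").write_text(io_formats.write_gtf(improved))
        (outdir / "transfrags.gtf").write_text(io_formats.write_transfrag_gtf(transfrags))
        (outdir / "counts.tsv").write_text(io_formats.write_counts(counts))
        (outdir / "ledger.json").write_text(
            json.dumps(ledger.to_json_dict(), indent=1, sort_keys=True))
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _cfg_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["repeat_classes"] = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
                           for r in cfg.repeat_classes]
    return d


def _tally(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return dict(sorted(out.items()))


def _transfrag_cpm(transfrags) -> dict[str, dict[str, float]]:
    totals: dict[str, float] = {}
    for tf in transfrags:
        for cond, a in tf.abundance.items():
            totals[cond] = totals.get(cond, 0.0) + a
    out = {}
    for tf in transfrags:
        out[tf.transfrag_id] = {
            cond: (a / totals[cond] * 1e6 if totals.get(cond) else 0.0)
            for cond, a in tf.abundance.items()
        }
    return out


def _gene_level(counts, truth):
    """Sum transcript counts to gene level."""
    gene_of = {m.transcript_id: m.gene_id for m in truth}
    df = counts.copy()
    df["__gene"] = [gene_of.get(t, t) for t in df.index]
    out = df.groupby("__gene").sum()
    out.index.name = "gene_id"
    return out[[s for s in SAMPLES]]
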