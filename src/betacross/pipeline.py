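"""Stage orchestration: each stage reads the previous stage's artifacts
from the output directory and writes its own, so stages can be run
individually or chained end to end. A run manifest (JSON) accumulates
the configuration, seeds, library versions and row counts per stage."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, annotate, diffmeth, directionality, enrichment, io, preprocess, synthetic, viz
from .config import PipelineConfig

logger = logging.getLogger(__name__)

ART = {
    "manifest": "manifest.tsv",
    "ground_truth": "ground_truth.tsv",
    "gmt": "gene_sets.gmt",
    "sheet": "sample_sheet.csv",
    "merged_beta": "merged_beta.tsv",
    "m_values": "m_values.tsv",
    "dmp": "dmp_table.tsv",
    "direction": "direction_table.tsv",
    "top_genes": "top_genes.tsv",
    "crosstab": "crosstab.tsv",
    "crosstab_counts": "crosstab_counts.tsv",
    "enrichment": "enrichment.tsv",
    "volcano": "volcano.png",
    "volcano_svg": "volcano.svg",
    "heatmap": "heatmap.png",
    "dendrogram": "dendrogram.png",
    "pca": "pca.png",
    "sampled_probes": "sampled_probes.tsv",
    "zscores": "zscore_matrix.tsv",
    "leaf_order": "leaf_orders.tsv",
    "pca_scores": "pca_scores.tsv",
    "run_manifest": "run_manifest.json",
}

# which stage produces which artifact, for actionable missing-input errors
_PRODUCER = {
    "manifest": "simulate",
    "ground_truth": "simulate",
    "gmt": "simulate",
    "sheet": "preprocess",
    "merged_beta": "preprocess",
    "m_values": "preprocess",
    "dmp": "dmp",
    "direction": "direction",
    "top_genes": "direction",
}


class MissingInputError(FileNotFoundError):
    pass


def _path(cfg: PipelineConfig, key: str) -> Path:
    return Path(cfg.out_dir) / ART[key]


def _require(cfg: PipelineConfig, key: str) -> Path:
    p = _path(cfg, key)
    if not p.exists():
        raise MissingInputError(
            f"missing input {p.name}; run the '{_PRODUCER[key]}' stage first"
        )
    return p


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent per-stage seed below 2^31 from the global seed."""
    stages = ["simulate", "gmt", "viz"]
    idx = stages.index(stage) if stage in stages else 99
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _update_run_manifest(cfg: PipelineConfig, stage: str, counts: dict) -> None:
    path = _path(cfg, "run_manifest")
    record = json.loads(path.read_text()) if path.exists() else {
        "config": dataclasses.asdict(
            dataclasses.replace(cfg, out_dir=str(cfg.out_dir))
        ),
        "versions": {
            "betacross": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "stages": {},
    }
    record["stages"][stage] = counts
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")


# ------------------------------------------------------------------ stages

def run_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulation, seed=stage_seed(cfg.seed, "simulate"))
    manifest = synthetic.generate_manifest(sim)
    beta, sheet, truth = synthetic.generate_beta(manifest, sim)
    io.write_manifest(manifest, _path(cfg, "manifest"))
    io.write_ground_truth(truth, _path(cfg, "ground_truth"))
    synthetic.generate_gmt(
        manifest, cfg.n_gmt_terms, cfg.n_gmt_enriched, sim, truth=truth, path=_path(cfg, "gmt")
    )
    matrices, sheets = synthetic.split_by_dataset(beta, sheet)
    for m, s in zip(matrices, sheets):
        ds = s["dataset_id"].iloc[0]
        io.write_matrix(m, out / f"beta_{ds}.tsv")
        io.write_sample_sheet(s, out / f"sheet_{ds}.csv")
    counts = {"probes": len(manifest), "samples": len(sheet), "datasets": len(matrices)}
    _update_run_manifest(cfg, "simulate", counts)
    return counts


def run_preprocess(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    beta_files = sorted(out.glob("beta_*.tsv"))
    if not beta_files:
        raise MissingInputError(
            "missing input beta_*.tsv matrices; run the 'simulate' stage first "
            "(or place beta/sheet files in the output directory)"
        )
    matrices = [io.read_matrix(p) for p in beta_files]
    sheets = [io.read_sample_sheet(out / f"sheet_{p.stem.split('_', 1)[1]}.csv") for p in beta_files]
    merged, sheet = preprocess.merge_datasets(matrices, sheets)
    filtered, removed = preprocess.filter_missing(merged, cfg.max_missing_fraction)
    m = preprocess.beta_to_m(filtered, cfg.m_epsilon)
    io.write_matrix(filtered, _path(cfg, "merged_beta"))
    io.write_matrix(m, _path(cfg, "m_values"))
    io.write_sample_sheet(sheet, _path(cfg, "sheet"))
    counts = {
        "probes_merged": len(merged),
        "probes_removed_missingness": removed,
        "probes_retained": len(filtered),
        "samples": len(sheet),
    }
    logger.info("preprocess: %s", counts)
    _update_run_manifest(cfg, "preprocess", counts)
    return counts


def run_dmp_stage(cfg: PipelineConfig) -> dict:
    m = io.read_matrix(_require(cfg, "m_values"))
    sheet = io.read_sample_sheet(_require(cfg, "sheet"))
    dmps = diffmeth.run_dmp(m, sheet, alpha=cfg.alpha)
    io.write_dmp_table(dmps, _path(cfg, "dmp"))
    counts = {
        "probes_tested": len(dmps),
        "significant": int(dmps["significant"].sum()),
    }
    _update_run_manifest(cfg, "dmp", counts)
    return counts


def _load_dmps(cfg: PipelineConfig) -> pd.DataFrame:
    dmps = io.read_dmp_table(_require(cfg, "dmp"))
    dmps["significant"] = dmps["adj.P.Val"] < cfg.alpha
    return dmps


def run_direction(cfg: PipelineConfig) -> dict:
    beta = io.read_matrix(_require(cfg, "merged_beta"))
    sheet = io.read_sample_sheet(_require(cfg, "sheet"))
    manifest = io.read_manifest(_require(cfg, "manifest"))
    dmps = _load_dmps(cfg)
    dirs = directionality.direction_table(beta, sheet, cutoff=cfg.beta_cutoff)
    dirs.reset_index().to_csv(_path(cfg, "direction"), sep="\t", index=False)
    top = directionality.rank_top_genes(dmps, dirs, manifest, n_top=cfg.n_top_genes)
    top.to_csv(_path(cfg, "top_genes"), sep="\t", index=False)
    sig_cls = dirs.loc[dirs.index.isin(dmps.loc[dmps["significant"], "probe_id"]), "change_class"]
    counts = {
        "significant_low_to_high": int((sig_cls == "low_to_high").sum()),
        "significant_high_to_low": int((sig_cls == "high_to_low").sum()),
        "top_gene_rows": len(top),
    }
    logger.info("direction: %s", counts)
    _update_run_manifest(cfg, "direction", counts)
    return counts


def run_crosstab(cfg: PipelineConfig) -> dict:
    manifest = io.read_manifest(_require(cfg, "manifest"))
    dmps = _load_dmps(cfg)
    dirs = pd.read_csv(_require(cfg, "direction"), sep="\t", index_col="probe_id")
    top = pd.read_csv(_require(cfg, "top_genes"), sep="\t")
    assignments = annotate.attach_annotation(dmps, manifest)
    table = annotate.crosstab(assignments, dirs, top_genes=top)
    table.to_csv(_path(cfg, "crosstab_counts"), sep="\t", index=False)
    annotate.write_crosstab(table, assignments, _path(cfg, "crosstab"))
    counts = {
        "assignments_significant": int(assignments["significant"].sum()),
        "strata_rows": len(table),
    }
    _update_run_manifest(cfg, "crosstab", counts)
    return counts


def run_enrich(cfg: PipelineConfig) -> dict:
    manifest = io.read_manifest(_require(cfg, "manifest"))
    dmps = _load_dmps(cfg)
    top = pd.read_csv(_require(cfg, "top_genes"), sep="\t")
    db = io.load_gmt(_require(cfg, "gmt"))
    mapping = directionality.explode_probe_genes(manifest)
    sig_probes = set(dmps.loc[dmps["significant"], "probe_id"])
    query = set(mapping.loc[mapping["probe_id"].isin(sig_probes), "gene"])
    universe = set(mapping["gene"])
    records = enrichment.ora_test(
        query, db, universe=universe,
        pvalue_cutoff=cfg.pvalue_cutoff, qvalue_cutoff=cfg.qvalue_cutoff,
    )
    ranked = enrichment.top_terms(records, n=cfg.n_top_terms)
    ranked = enrichment.intersect_top_genes(ranked, top)
    enrichment.write_enrichment_table(ranked, _path(cfg, "enrichment"))
    counts = {
        "query_genes": len(query),
        "universe_genes": len(universe),
        "terms_significant": len(records),
        "terms_reported": len(ranked),
    }
    _update_run_manifest(cfg, "enrich", counts)
    return counts


def run_viz(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    beta = io.read_matrix(_require(cfg, "merged_beta"))
    sheet = io.read_sample_sheet(_require(cfg, "sheet"))
    dmps = _load_dmps(cfg)
    viz.volcano(dmps, _path(cfg, "volcano"), alpha=cfg.alpha)
    viz.volcano(dmps, _path(cfg, "volcano_svg"), alpha=cfg.alpha)

    sig = list(dmps.loc[dmps["significant"], "probe_id"])
    sampled = viz.sample_significant(sig, n=cfg.n_heatmap_cpgs, seed=stage_seed(cfg.seed, "viz"))
    pd.Series(sampled, name="probe_id").to_csv(_path(cfg, "sampled_probes"), sep="\t", index=False)
    z, dropped = viz.zscore_rows(beta.loc[sampled])
    io.write_matrix(z, _path(cfg, "zscores"))
    viz.heatmap(z, sheet, _path(cfg, "heatmap"))
    viz.dendrogram_plot(z, sheet, _path(cfg, "dendrogram"))
    _, col_order = viz.hierarchical_cluster(z, axis="columns")
    _, row_order = viz.hierarchical_cluster(z, axis="rows")
    with open(_path(cfg, "leaf_order"), "w") as fh:
        fh.write("axis\tleaf_order\n")
        fh.write("columns\t" + ";".join(map(str, col_order)) + "\n")
        fh.write("rows\t" + ";".join(map(str, row_order)) + "\n")
    result = viz.pca_samples(z)
    result.scores.iloc[:, :10].assign(
        variance_fraction_pc1=result.variance_fraction[0],
        variance_fraction_pc2=result.variance_fraction[1],
    ).to_csv(_path(cfg, "pca_scores"), sep="\t")
    viz.pca_plot(result, sheet, _path(cfg, "pca"))
    counts = {
        "sampled_probes": len(sampled),
        "zscore_rows": len(z),
        "zscore_rows_dropped": dropped,
        "pc1_variance_fraction": float(result.variance_fraction[0]),
    }
    del out
    _update_run_manifest(cfg, "viz", counts)
    return counts


STAGES = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "dmp": run_dmp_stage,
    "direction": run_direction,
    "crosstab": run_crosstab,
    "enrich": run_enrich,
    "viz": run_viz,
}

STAGE_ORDER = ["simulate", "preprocess", "dmp", "direction", "crosstab", "enrich", "viz"]


def run_all(cfg: PipelineConfig) -> dict:
    counts = {}
    for name in STAGE_ORDER:
        counts[name] = STAGES[name](cfg)
    return counts
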