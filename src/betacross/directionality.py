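"""Group-level methylation-state calls and beta = 0.5 threshold-crossing classes.

A CpG's state in each group is high (group-mean beta >= 0.5, boundary
inclusive) or low (< 0.5). Crossing the boundary between groups defines
the two directionality classes of interest — low_to_high (control low,
case high) and high_to_low — while non-crossing CpGs are stable_high /
stable_low. Genes are then ranked within each crossing direction by the
absolute per-gene mean logFC of their qualifying CpGs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import GROUP_CASE, GROUP_CONTROL, split_multi

logger = logging.getLogger(__name__)

BETA_CUTOFF = 0.5
CROSSING_CLASSES = ("low_to_high", "high_to_low")
UNCLASSIFIABLE = "unclassifiable"


def group_mean_beta(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean beta over observed entries, separately per group.

    Probes with no observed value in a group get NaN for that group and
    are unclassifiable downstream (never silently dropped).
    """
    ctrl_cols = list(sheet.loc[sheet["group"] == GROUP_CONTROL, "sample_id"])
    case_cols = list(sheet.loc[sheet["group"] == GROUP_CASE, "sample_id"])
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "mean_beta_control": beta[ctrl_cols].mean(axis=1, skipna=True),
                "mean_beta_case": beta[case_cols].mean(axis=1, skipna=True),
            }
        )
    return out


def classify_change(
    mean_control: float, mean_case: float, cutoff: float = BETA_CUTOFF
) -> str:
    """Classify one (control, case) pair of group-mean betas.

    high state is boundary inclusive (beta >= cutoff). Crossing pairs
    map to low_to_high / high_to_low; non-crossing pairs to
    stable_high / stable_low; a missing mean yields 'unclassifiable'.
    """
    if mean_control is None or mean_case is None:
        return UNCLASSIFIABLE
    if isinstance(mean_control, float) and math.isnan(mean_control):
        return UNCLASSIFIABLE
    if isinstance(mean_case, float) and math.isnan(mean_case):
        return UNCLASSIFIABLE
    high_control = mean_control >= cutoff
    high_case = mean_case >= cutoff
    if not high_control and high_case:
        return "low_to_high"
    if high_control and not high_case:
        return "high_to_low"
    return "stable_high" if high_case else "stable_low"


def direction_table(
    beta: pd.DataFrame, sheet: pd.DataFrame, cutoff: float = BETA_CUTOFF
) -> pd.DataFrame:
    """Per-probe DirectionRecord table: group means, states, change class."""
    means = group_mean_beta(beta, sheet)
    mc = means["mean_beta_control"].to_numpy(float)
    mp = means["mean_beta_case"].to_numpy(float)
    state_c = np.where(np.isnan(mc), "unknown", np.where(mc >= cutoff, "high", "low"))
    state_p = np.where(np.isnan(mp), "unknown", np.where(mp >= cutoff, "high", "low"))
    cls = np.array(
        [classify_change(a, b, cutoff) for a, b in zip(mc, mp)], dtype=object
    )
    out = means.copy()
    out["state_control"] = state_c
    out["state_case"] = state_p
    out["change_class"] = cls
    out.index.name = "probe_id"
    return out


def explode_probe_genes(annotation: pd.DataFrame) -> pd.DataFrame:
    """One row per (probe, gene, refgene group) mapping; all mappings retained.

    Probes with an empty gene list are omitted here (they carry no gene
    to rank or enrich).
    """
    rows = []
    for rec in annotation.itertuples(index=False):
        genes = split_multi(rec.UCSC_RefGene_Name)
        groups = split_multi(rec.UCSC_RefGene_Group)
        refseqs = split_multi(rec.RefSeq_ID)
        for i, gene in enumerate(genes):
            rows.append(
                {
                    "probe_id": rec.IlmnID,
                    "gene": gene,
                    "refgene_group": groups[i] if i < len(groups) else "",
                    "refseq_id": refseqs[i] if i < len(refseqs) else "",
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "gene", "refgene_group", "refseq_id"])


def rank_top_genes(
    dmps: pd.DataFrame,
    directions: pd.DataFrame,
    annotation: pd.DataFrame,
    n_top: int = 20,
    ranking: str = "mean",
) -> pd.DataFrame:
    """Top genes by |logFC| within each crossing direction.

    Restricted to significant probes whose change class is a boundary
    crossing; probe-to-gene mappings are exploded (a probe annotated to
    k genes contributes to k genes). Per (gene, direction) the logFC and
    the group-mean betas are averaged over the qualifying CpGs; genes
    are sorted by |mean logFC| descending (``ranking='max'`` ranks by
    the largest per-CpG |logFC| instead), ties broken by gene symbol.
    """
    if ranking not in ("mean", "max"):
        raise ValueError("ranking must be 'mean' or 'max'")
    sig = dmps.loc[dmps["significant"], ["probe_id", "logFC"]]
    dirs = directions.reset_index()[
        ["probe_id", "mean_beta_control", "mean_beta_case", "change_class"]
    ]
    probes = sig.merge(dirs, on="probe_id")
    probes = probes[probes["change_class"].isin(CROSSING_CLASSES)]
    if probes.empty:
        logger.warning("rank_top_genes: no significant threshold-crossing probes")
        return pd.DataFrame(
            columns=[
                "direction",
                "gene_symbol",
                "mean_logFC",
                "mean_beta_control",
                "mean_beta_case",
                "cpg_ids",
                "refseq_ids",
            ]
        )
    mapping = explode_probe_genes(annotation)
    merged = probes.merge(mapping, on="probe_id")

    out_rows = []
    for (direction, gene), grp in merged.groupby(["change_class", "gene"], sort=False):
        uniq = grp.drop_duplicates("probe_id").sort_values("probe_id")
        key = uniq["logFC"].mean()
        if ranking == "max":
            key = uniq.loc[uniq["logFC"].abs().idxmax(), "logFC"]
        refseqs = sorted({r for r in grp["refseq_id"] if r})
        out_rows.append(
            {
                "direction": direction,
                "gene_symbol": gene,
                "mean_logFC": uniq["logFC"].mean(),
                "rank_key": abs(key),
                "mean_beta_control": uniq["mean_beta_control"].mean(),
                "mean_beta_case": uniq["mean_beta_case"].mean(),
                "cpg_ids": ";".join(uniq["probe_id"]),
                "refseq_ids": ";".join(refseqs),
            }
        )
    table = pd.DataFrame(out_rows)
    parts = []
    for direction in CROSSING_CLASSES:
        block = table[table["direction"] == direction].sort_values(
            ["rank_key", "gene_symbol"], ascending=[False, True], kind="mergesort"
        )
        parts.append(block.head(n_top))
    result = pd.concat(parts, ignore_index=True).drop(columns="rank_key")
    return result
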