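"""Probe annotation joins and the stratified island x gene-structure cross-tab.

The counting unit throughout is the CpG-feature *assignment*: a probe
annotated to k (gene, gene-structure) pairs contributes k assignments,
and an unannotated probe contributes a single Unknown-group assignment,
so that all retained probe-gene mappings are preserved. The cross-tab
stratifies significant assignments by island relation, gene-structure
group and case-group methylation state, and counts within each stratum
the assignments whose group-mean beta crossed the 0.5 boundary in the
state-consistent direction (high state pairs with low -> high crossings,
low state with high -> low).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import split_multi

ISLAND_ORDER = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea", "Unknown"]
REFGENE_ORDER = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "Unknown"]

_STATE_LABEL = {"high": "High-methylation", "low": "Low-methylation"}
_STATE_TO_CROSSING = {"high": "low_to_high", "low": "high_to_low"}


class AnnotationError(ValueError):
    """Raised when the manifest cannot be joined consistently."""


def ordered_categories() -> tuple[list[str], list[str]]:
    """Canonical row orders: island relations by proximity to the island,
    gene-structure groups by proximity to the transcription start site;
    both end with Unknown."""
    return list(ISLAND_ORDER), list(REFGENE_ORDER)


def attach_annotation(dmps: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Left-join DMP records with the manifest, exploded per (gene, group) pair.

    Probes absent from the manifest get Unknown island relation and
    Unknown gene-structure group; a probe with an empty gene list gets a
    single assignment with blank gene and Unknown group. Duplicate
    manifest rows for one probe are an error.
    """
    dup = manifest["IlmnID"][manifest["IlmnID"].duplicated()]
    if len(dup):
        raise AnnotationError(f"duplicate manifest rows for probes: {sorted(set(dup))}")
    man = manifest.set_index("IlmnID")

    dmps = dmps.rename(columns={"adj.P.Val": "adj_p"})
    if "adj_p" not in dmps.columns:
        dmps = dmps.assign(adj_p=np.nan)
    rows = []
    for rec in dmps.itertuples(index=False):
        probe = rec.probe_id
        if probe in man.index:
            mrow = man.loc[probe]
            island = mrow["Relation_to_Island"] or "Unknown"
            genes = split_multi(mrow["UCSC_RefGene_Name"])
            groups = split_multi(mrow["UCSC_RefGene_Group"])
        else:
            island, genes, groups = "Unknown", [], []
        if not genes:
            pairs = [("", "Unknown")]
        else:
            pairs = [
                (g, groups[i] if i < len(groups) and groups[i] else "Unknown")
                for i, g in enumerate(genes)
            ]
        for gene, group in pairs:
            rows.append(
                {
                    "probe_id": probe,
                    "logFC": rec.logFC,
                    "adj_p": rec.adj_p,
                    "significant": rec.significant,
                    "gene": gene,
                    "refgene_group": group,
                    "relation_to_island": island,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "logFC",
            "adj_p",
            "significant",
            "gene",
            "refgene_group",
            "relation_to_island",
        ],
    )
    return out


def format_percent(value: float) -> str:
    """Render a percentage: exact zero as 0.00, positive values below
    0.005 as '< 0.01', otherwise two decimals."""
    if value == 0:
        return "0.00"
    if value < 0.005:
        return "< 0.01"
    return f"{value:.2f}"


def island_percentages(assignments: pd.DataFrame) -> pd.Series:
    """Share of assignments per island relation (percent), canonical order."""
    counts = assignments["relation_to_island"].value_counts()
    total = counts.sum()
    return pd.Series(
        [100.0 * counts.get(cat, 0) / total if total else 0.0 for cat in ISLAND_ORDER],
        index=ISLAND_ORDER,
    )


def crosstab(
    annotated: pd.DataFrame,
    directions: pd.DataFrame,
    top_genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stratified cross-tab of significant CpG-feature assignments.

    One row per (island relation, gene-structure group, case state)
    stratum with at least one assignment at the (island, group) level;
    rows follow the canonical category orders. ``state_count`` counts
    all significant assignments whose case-group state matches the row
    (these partition the assignments); ``cpg_count`` counts the subset
    whose change class is the state-consistent boundary crossing.
    Percentages use the total number of significant assignments as
    denominator. ``gene_labels`` lists top-ranked genes having at least
    one qualifying crossing CpG assignment in the cell.
    """
    sig = annotated[annotated["significant"]].copy()
    dirs = directions.reset_index()[["probe_id", "state_case", "change_class"]]
    sig = sig.merge(dirs, on="probe_id", how="left")
    total = len(sig)

    top_lookup: dict[str, set[str]] = {}
    if top_genes is not None and len(top_genes):
        for rec in top_genes.itertuples(index=False):
            top_lookup.setdefault(rec.direction, set()).add(rec.gene_symbol)

    rows = []
    for island in ISLAND_ORDER:
        isl = sig[sig["relation_to_island"] == island]
        if isl.empty:
            continue
        for group in REFGENE_ORDER:
            cell = isl[isl["refgene_group"] == group]
            if cell.empty:
                continue
            for state in ("high", "low"):
                in_state = cell[cell["state_case"] == state]
                crossing_class = _STATE_TO_CROSSING[state]
                crossing = in_state[in_state["change_class"] == crossing_class]
                labels = sorted(
                    set(crossing["gene"]) & top_lookup.get(crossing_class, set())
                )
                rows.append(
                    {
                        "relation_to_island": island,
                        "refgene_group": group,
                        "state": state,
                        "state_count": len(in_state),
                        "percent_of_total": 100.0 * len(in_state) / total if total else 0.0,
                        "change_class": crossing_class,
                        "cpg_count": len(crossing),
                        "percent_of_change": 100.0 * len(crossing) / total if total else 0.0,
                        "gene_labels": ";".join(labels),
                    }
                )
    return pd.DataFrame(rows)


def write_crosstab(table: pd.DataFrame, assignments: pd.DataFrame, path) -> None:
    """Write the cross-tab in the published table shape (formatted percents)."""
    isl_pct = island_percentages(assignments[assignments["significant"]])
    change_label = {"low_to_high": "Control low -> Periodontitis high",
                    "high_to_low": "Control high -> Periodontitis low"}
    out = pd.DataFrame(
        {
            "Relation_to_Island": [
                f"{r} ({isl_pct[r]:.2f}%)" for r in table["relation_to_island"]
            ],
            "UCSC_RefGene_Group": table["refgene_group"],
            "Methylation_state": [_STATE_LABEL[s] for s in table["state"]],
            "Percent_of_total": [format_percent(v) for v in table["percent_of_total"]],
            "Methylation_Status_Change": [change_label[c] for c in table["change_class"]],
            "Percent_of_change": [format_percent(v) for v in table["percent_of_change"]],
            "CpG_count": table["cpg_count"],
            "UCSC_RefGene_Name": table["gene_labels"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
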