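"""Volcano plot, Z-score heatmap with hierarchical clustering, dendrogram, PCA.

Unsupervised views operate on a reproducible random sample of
significant CpGs (default 10,000), row-standardized to Z-scores with
the n-1 sample standard deviation. Clustering uses Euclidean distance
with complete linkage on both axes; PCA of samples applies centering
only (rows are already standardized). Group colors follow the blue =
Control / red = Periodontitis convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import GROUP_CONTROL

logger = logging.getLogger(__name__)

GROUP_COLORS = {"Control": "#1f77b4", "Periodontitis": "#d62728"}


def volcano(
    dmps: pd.DataFrame,
    path: str | Path,
    alpha: float = 0.05,
    p_floor: float = 1e-300,
) -> None:
    """Volcano plot: logFC vs -log10(adjusted p), all probes plotted.

    A dashed horizontal line marks -log10(alpha) (~1.301 at 0.05); no
    vertical logFC threshold lines are drawn. Adjusted p-values are
    clipped at ``p_floor`` before the log transform.
    """
    if dmps.empty:
        raise ValueError("DMP table is empty")
    x = dmps["logFC"].to_numpy(float)
    y = -np.log10(np.clip(dmps["adj.P.Val"].to_numpy(float), p_floor, None))
    sig = dmps["adj.P.Val"].to_numpy(float) < alpha
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x[~sig], y[~sig], s=3, c="#888888", alpha=0.5, linewidths=0, label="not significant")
    ax.scatter(x[sig], y[sig], s=3, c="#d62728", alpha=0.6, linewidths=0, label="significant")
    ax.axhline(-np.log10(alpha), linestyle="--", color="black", linewidth=1)
    ax.set_xlabel("logFC (M scale, case - control)")
    ax.set_ylabel("-log10 adjusted p-value")
    ax.legend(frameon=False, markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sample_significant(probe_ids, n: int = 10_000, seed: int = 0) -> list[str]:
    """Uniform sample of probe ids without replacement, reproducible by seed.

    If n is at least the population size, all ids are returned (warned).
    """
    probe_ids = list(probe_ids)
    if n >= len(probe_ids):
        if n > len(probe_ids):
            logger.warning(
                "sample_significant: requested %d of %d probes; returning all", n, len(probe_ids)
            )
        return probe_ids
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(probe_ids), size=n, replace=False)
    return [probe_ids[i] for i in sorted(idx)]


def zscore_rows(beta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Standardize each row to mean 0 / sd 1 (sample sd, n-1 denominator).

    Rows with fewer than 2 observed values or zero variance are dropped
    (returned count); missing entries stay missing.
    """
    values = beta.to_numpy(float)
    n_obs = np.sum(~np.isnan(values), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    keep = (n_obs >= 2) & (sd > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zscore_rows: dropped %d constant or underpopulated rows", dropped)
    z = (values[keep] - mean[keep, None]) / sd[keep, None]
    return pd.DataFrame(z, index=beta.index[keep], columns=beta.columns), dropped


def _impute_row_means(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    row_mean = np.nanmean(out, axis=1)
    rows, cols = np.where(np.isnan(out))
    out[rows, cols] = row_mean[rows]
    return out


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "columns"):
    """Complete-linkage agglomeration over Euclidean distances.

    axis='columns' clusters samples, axis='rows' clusters probes.
    Missing values are mean-imputed per probe row before distances.
    Returns (linkage matrix, leaf order as item labels).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    values = _impute_row_means(matrix.to_numpy(float))
    items = matrix.index if axis == "rows" else matrix.columns
    data = values if axis == "rows" else values.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(link)
    return link, [items[i] for i in order]


def cut_two_clusters(link: np.ndarray) -> np.ndarray:
    """Labels (1/2) of the two-cluster cut of a linkage tree."""
    return hierarchy.fcluster(link, t=2, criterion="maxclust")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray


def pca_samples(matrix: pd.DataFrame) -> PcaResult:
    """PCA of samples over probes, centering only (rows pre-standardized).

    Returns per-sample scores and the per-component variance fractions
    (non-increasing, summing to 1 over the full decomposition).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    data = _impute_row_means(matrix.to_numpy(float)).T  # samples x probes
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        u * s,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PcaResult(scores=scores, variance_fraction=frac)


# ----------------------------------------------------------------- figures

def _group_color(sheet: pd.DataFrame) -> dict[str, str]:
    return {
        row.sample_id: GROUP_COLORS.get(
            "Control" if row.group == GROUP_CONTROL else "Periodontitis", "#333333"
        )
        for row in sheet.itertuples(index=False)
    }


def heatmap(matrix: pd.DataFrame, sheet: pd.DataFrame, path: str | Path) -> None:
    """Clustered heatmap (rows and columns) with group color annotation."""
    _, row_order = hierarchical_cluster(matrix, axis="rows")
    _, col_order = hierarchical_cluster(matrix, axis="columns")
    data = _impute_row_means(matrix.loc[row_order, col_order].to_numpy(float))
    colors = _group_color(sheet)
    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(8, 8), gridspec_kw={"height_ratios": [1, 30]}, sharex=True
    )
    ax.imshow(data, aspect="auto", cmap="coolwarm", interpolation="nearest")
    for j, sample in enumerate(col_order):
        ax_bar.add_patch(plt.Rectangle((j - 0.5, 0), 1, 1, color=colors.get(sample, "#333333")))
    ax_bar.set_xlim(-0.5, len(col_order) - 0.5)
    ax_bar.set_ylim(0, 1)
    ax_bar.axis("off")
    ax.set_xlabel("samples (clustered)")
    ax.set_ylabel("CpGs (clustered)")
    ax.set_yticks([])
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dendrogram_plot(matrix: pd.DataFrame, sheet: pd.DataFrame, path: str | Path) -> None:
    """Sample dendrogram with leaf labels colored by group."""
    link, _ = hierarchical_cluster(matrix, axis="columns")
    colors = _group_color(sheet)
    fig, ax = plt.subplots(figsize=(10, 4))
    dn = hierarchy.dendrogram(link, labels=list(matrix.columns), ax=ax, leaf_font_size=6)
    for label in ax.get_xmajorticklabels():
        label.set_color(colors.get(label.get_text(), "#333333"))
    ax.set_ylabel("Euclidean distance (complete linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_plot(result: PcaResult, sheet: pd.DataFrame, path: str | Path) -> None:
    """Scatter of the first two components, axes labelled with variance shares."""
    colors = _group_color(sheet)
    fig, ax = plt.subplots(figsize=(6, 5))
    for row in sheet.itertuples(index=False):
        xy = result.scores.loc[row.sample_id]
        ax.scatter(xy["PC1"], xy["PC2"], c=colors[row.sample_id], s=18)
    ax.set_xlabel(f"PC1 ({100 * result.variance_fraction[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * result.variance_fraction[1]:.1f}%)")
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=c, label=g)
        for g, c in GROUP_COLORS.items()
    ]
    ax.legend(handles=handles, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
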