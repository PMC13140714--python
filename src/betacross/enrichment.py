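"""Hypergeometric over-representation analysis over GMT gene sets.

For each term, with universe size N, term size K (restricted to the
universe), query size n and overlap k, the p-value is the upper tail
P(X >= k) of the hypergeometric distribution. Derived statistics use
the standard vocabulary:

* GeneRatio = k/n, BgRatio = K/N
* RichFactor = k/K (overlap over term size)
* FoldEnrichment = (k/n)/(K/N) (observed over expected overlap)
* zScore = (k - nK/N) / sqrt(n (K/N)(1 - K/N)(N - n)/(N - 1)),
  i.e. the overlap standardized by the hypergeometric mean and
  variance with finite-population correction.

p-values are BH-adjusted across tested terms; the reported q-value
defaults to the BH value. Reported terms satisfy p.adjust < 0.05 and
q < 0.2 by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_bh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatioStats:
    gene_ratio: float
    bg_ratio: float
    rich_factor: float
    fold_enrichment: float
    z_score: float


def derive_statistics(k: int, n: int, K: int, N: int) -> RatioStats:
    """Ratio statistics and z-score from the contingency counts.

    k: overlap, n: query size, K: term size, N: universe size.
    """
    if not (0 <= k <= min(n, K) and N >= max(n, K)):
        raise ValueError(f"invalid counts: k={k}, n={n}, K={K}, N={N}")
    if K == 0 or n == 0:
        return RatioStats(math.nan, math.nan, math.nan, math.nan, math.nan)
    gene_ratio = k / n
    bg_ratio = K / N
    rich_factor = k / K
    fold_enrichment = gene_ratio / bg_ratio
    var = n * bg_ratio * (1.0 - bg_ratio) * (N - n) / (N - 1)
    z = (k - n * bg_ratio) / math.sqrt(var) if var > 0 else math.nan
    return RatioStats(gene_ratio, bg_ratio, rich_factor, fold_enrichment, z)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(
    query: set[str],
    db: dict[str, tuple[str, list[str]]],
    universe: set[str] | None = None,
    pvalue_cutoff: float = 0.05,
    qvalue_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Over-representation test of ``query`` against every term in ``db``.

    The universe defaults to the union of all term members. Query genes
    outside the universe are dropped (logged count); terms with no
    member in the universe are skipped. Returns the surviving records
    (p.adjust < pvalue_cutoff and q < qvalue_cutoff) with all derived
    statistics; the unfiltered table is available via
    ``ora_test(...).attrs['all_terms']``.
    """
    if not query:
        raise ValueError("query gene set is empty")
    if universe is None:
        universe = set().union(*(set(genes) for _, genes in db.values()))
    if not universe:
        raise ValueError("universe is empty")
    dropped = len(set(query) - universe)
    if dropped:
        logger.info("ora_test: dropped %d query genes absent from the universe", dropped)
    query_in = set(query) & universe
    if not query_in:
        raise ValueError("no query gene lies in the universe")

    N, n = len(universe), len(query_in)
    rows = []
    for term, (desc, members) in db.items():
        term_in = set(members) & universe
        K = len(term_in)
        if K == 0:
            continue
        overlap = term_in & query_in
        k = len(overlap)
        p = hypergeom_upper_tail(k, N, K, n)
        st = derive_statistics(k, n, K, N)
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": p,
                "gene_ratio": st.gene_ratio,
                "bg_ratio": st.bg_ratio,
                "rich_factor": st.rich_factor,
                "fold_enrichment": st.fold_enrichment,
                "z_score": st.z_score,
                "overlap_genes": ";".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = adjust_bh(table["p_value"].to_numpy())
    table["q_value"] = table["p_adjusted"]
    kept = table[
        (table["p_adjusted"] < pvalue_cutoff) & (table["q_value"] < qvalue_cutoff)
    ].reset_index(drop=True)
    kept.attrs["all_terms"] = table
    return kept


def top_terms(records: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """First n records by ascending p-value (ties: p.adjust, then term id),
    with a 1-based rank column."""
    if records.empty:
        out = records.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    ordered = records.sort_values(
        ["p_value", "p_adjusted", "term_id"], kind="mergesort"
    ).head(n)
    ordered = ordered.reset_index(drop=True)
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    return ordered


def intersect_top_genes(records: pd.DataFrame, top_genes: pd.DataFrame) -> pd.DataFrame:
    """Fill ``top_gene_overlap``: overlap genes that are also top-ranked genes."""
    symbols = set(top_genes["gene_symbol"]) if len(top_genes) else set()
    out = records.copy()
    out["top_gene_overlap"] = [
        "/".join(sorted(set(x.split(";")) & symbols)) if x else ""
        for x in out["overlap_genes"]
    ]
    return out


TABLE_COLUMNS = [
    "rank",
    "ID",
    "Description",
    "geneID",
    "pvalue",
    "p.adjust",
    "qvalue",
    "RichFactor",
    "FoldEnrichment",
    "zScore",
    "GeneRatio",
    "BgRatio",
    "Count",
]


def write_enrichment_table(records: pd.DataFrame, path) -> None:
    """Write ranked enrichment records in the published table shape."""
    if records.empty:
        pd.DataFrame(columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    out = pd.DataFrame(
        {
            "rank": records["rank"],
            "ID": records["term_id"],
            "Description": records["description"],
            "geneID": records.get("top_gene_overlap", ""),
            "pvalue": records["p_value"],
            "p.adjust": records["p_adjusted"],
            "qvalue": records["q_value"],
            "RichFactor": records["rich_factor"],
            "FoldEnrichment": records["fold_enrichment"],
            "zScore": records["z_score"],
            "GeneRatio": [f"{k}/{n}" for k, n in zip(records["k"], records["n"])],
            "BgRatio": [f"{K}/{N}" for K, N in zip(records["K"], records["N"])],
            "Count": records["k"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
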