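"""Synthetic 450K-style methylation study generator with ground truth.

The generator emulates the statistical structure the analysis assumes:

* bimodal beta values (low mode near 0.15, high mode near 0.85, plus a
  mid component near 0.5 so that threshold crossings are attainable);
* a two-group design (Control vs Periodontitis) split over several
  dataset blocks;
* planted differentially methylated probes, a subset of which cross the
  beta = 0.5 boundary in a stated direction (group-level low -> high or
  high -> low);
* probe-level missingness, including probes engineered to exceed the
  80% missingness filter;
* many-to-many probe <-> gene mappings and unannotated probes.

Group means are planted on the M (base-2 logit) scale and per-sample
noise is Gaussian on that scale; betas are the inverse-logit images, so
every generated value lies strictly inside (0, 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ISLAND_CATEGORIES, ConfigError, SimulationConfig
from .io import GROUP_CASE, GROUP_CONTROL, MANIFEST_COLUMNS, write_gmt
from .preprocess import m_to_beta

REFGENE_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

# probability a probe maps to 0 / 1 / 2 genes
_GENE_COUNT_PROBS = (0.25, 0.60, 0.15)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate an Illumina-450K-shaped probe annotation manifest.

    Island-relation categories are drawn per ``config.island_proportions``;
    gene symbols are synthetic tokens (G000001...), some probes map to
    two genes and some genes own several probes; RefSeq ids mirror the
    gene symbols. Reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probes = _probe_ids(n)

    probs = np.array([config.island_proportions[c] for c in ISLAND_CATEGORIES])
    relation = rng.choice(ISLAND_CATEGORIES, size=n, p=probs / probs.sum())

    n_genes = max(1, n // 3)
    gene_pool = np.array([f"G{i + 1:06d}" for i in range(n_genes)])
    refseq_pool = np.array([f"NM_{i + 1:06d}" for i in range(n_genes)])
    gene_counts = rng.choice([0, 1, 2], size=n, p=_GENE_COUNT_PROBS)

    names, groups, refseqs = [], [], []
    for k in gene_counts:
        if k == 0:
            names.append("")
            groups.append("")
            refseqs.append("")
            continue
        idx = rng.choice(n_genes, size=k, replace=False)
        grp = rng.choice(REFGENE_GROUPS, size=k)
        names.append(";".join(gene_pool[idx]))
        groups.append(";".join(grp))
        refseqs.append(";".join(refseq_pool[idx]))

    manifest = pd.DataFrame(
        {
            "IlmnID": probes,
            "CHR": rng.integers(1, 23, size=n).astype(str),
            "MAPINFO": rng.integers(1, 200_000_000, size=n),
            "UCSC_RefGene_Name": names,
            "UCSC_RefGene_Group": groups,
            "Relation_to_Island": relation,
            "RefSeq_ID": refseqs,
        },
        columns=MANIFEST_COLUMNS,
    )
    return manifest


def _baseline_m(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal-plus-mid baseline on the M scale (modes ~0.15 / ~0.85 / ~0.5 beta)."""
    comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
    centers = np.array([-2.5, 2.5, 0.0])
    return rng.normal(centers[comp], 0.7)


def generate_beta(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (beta matrix, sample sheet, ground truth) for a manifest.

    Planted low_to_high probes have a true control mean beta < 0.5 and a
    true case mean beta >= 0.5 (symmetrically for high_to_low);
    non-crossing planted effects are pushed away from the boundary so
    the planted class is exact by construction. Missingness is injected
    at ``missing_rate`` plus ``frac_high_missing_probes`` probes with
    strictly more than 80% missing entries.
    """
    config.validate()
    if len(manifest) == 0:
        raise ValueError("manifest must be nonempty")
    if config.n_control + config.n_case < 4:
        raise ValueError("need at least 4 samples total for variance estimation")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    probes = manifest["IlmnID"].to_numpy()
    n = len(probes)
    n_ctrl, n_case = config.n_control, config.n_case
    n_samples = n_ctrl + n_case

    perm = rng.permutation(n)
    n_dmp = int(round(config.frac_dmp * n))
    n_lh = int(round(config.frac_crossing_low_high * n))
    n_hl = int(round(config.frac_crossing_high_low * n))
    n_lh = min(n_lh, n_dmp)
    n_hl = min(n_hl, n_dmp - n_lh)
    idx_lh = perm[:n_lh]
    idx_hl = perm[n_lh : n_lh + n_hl]
    idx_other_dmp = perm[n_lh + n_hl : n_dmp]
    idx_null = perm[n_dmp:]

    effect = config.effect_size_m
    ctrl_m = np.empty(n)
    case_m = np.empty(n)

    base = _baseline_m(rng, n)
    ctrl_m[:] = base
    case_m[:] = base

    # crossing probes: control drawn close enough to M = 0 that the
    # planted shift lands the case mean on the other side of beta = 0.5
    span = 0.9 * min(effect, 1.3) if effect > 0 else 0.0
    if n_lh:
        ctrl_m[idx_lh] = rng.uniform(-max(span, 1e-3), -0.02, size=n_lh)
        case_m[idx_lh] = ctrl_m[idx_lh] + effect
    if n_hl:
        ctrl_m[idx_hl] = rng.uniform(0.02, max(span, 1e-3), size=n_hl)
        case_m[idx_hl] = ctrl_m[idx_hl] - effect
    if len(idx_other_dmp):
        # shift away from the boundary so these never cross
        away = np.where(base[idx_other_dmp] >= 0.0, effect, -effect)
        case_m[idx_other_dmp] = base[idx_other_dmp] + away

    planted_class = np.full(n, "stable", dtype=object)
    planted_class[idx_lh] = "low_to_high"
    planted_class[idx_hl] = "high_to_low"
    is_dmp = np.zeros(n, dtype=bool)
    is_dmp[perm[:n_dmp]] = True
    del idx_null

    sample_ids = [f"CTL{i + 1:03d}" for i in range(n_ctrl)] + [
        f"PER{i + 1:03d}" for i in range(n_case)
    ]
    group = [GROUP_CONTROL] * n_ctrl + [GROUP_CASE] * n_case
    dataset = [f"DS{(i % config.n_datasets) + 1}" for i in range(n_ctrl)] + [
        f"DS{(i % config.n_datasets) + 1}" for i in range(n_case)
    ]
    sheet = pd.DataFrame({"sample_id": sample_ids, "group": group, "dataset_id": dataset})

    means = np.concatenate(
        [np.repeat(ctrl_m[:, None], n_ctrl, axis=1), np.repeat(case_m[:, None], n_case, axis=1)],
        axis=1,
    )
    m_values = means + rng.normal(0.0, config.within_group_sd_m, size=(n, n_samples))
    if config.batch_shift_m:
        ds_index = np.array([int(d[2:]) - 1 for d in dataset])
        centered = ds_index - ds_index.mean()
        m_values = m_values + config.batch_shift_m * centered[None, :]
    beta = m_to_beta(m_values)

    # missingness: background rate everywhere, plus engineered probes
    mask = rng.random((n, n_samples)) < config.missing_rate
    n_high = int(round(config.frac_high_missing_probes * n))
    if n_high:
        # engineer high-missing probes among non-planted ones when possible
        candidates = perm[n_dmp:] if n - n_dmp >= n_high else perm
        high_idx = candidates[:n_high]
        floor = int(np.floor(0.8 * n_samples)) + 1
        for i in high_idx:
            k = int(rng.integers(floor, n_samples + 1))
            cols = rng.choice(n_samples, size=k, replace=False)
            mask[i, :] = False
            mask[i, cols] = True
    beta[mask] = np.nan

    beta_df = pd.DataFrame(beta, index=pd.Index(probes, name="probe_id"), columns=sample_ids)
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "is_dmp": is_dmp,
            "planted_class": planted_class,
            "true_mean_beta_control": m_to_beta(ctrl_m),
            "true_mean_beta_case": m_to_beta(case_m),
            "true_mean_m_control": ctrl_m,
            "true_mean_m_case": case_m,
        }
    )
    return beta_df, sheet, truth


def generate_gmt(
    manifest: pd.DataFrame,
    n_terms: int,
    enriched_terms: int,
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
    path=None,
    planted_member_fraction: float = 0.8,
) -> dict[str, tuple[str, list[str]]]:
    """Generate gene sets over the manifest's gene universe.

    The first ``enriched_terms`` sets draw ``planted_member_fraction``
    of their members from genes annotated to planted differential
    probes (requires ``truth``), so over-representation is detectable.
    Writes standard GMT when ``path`` is given.
    """
    if n_terms < enriched_terms:
        raise ConfigError("n_terms must be >= enriched_terms")
    genes = sorted(
        {g for field in manifest["UCSC_RefGene_Name"] for g in str(field).split(";") if g}
    )
    if not genes:
        raise ValueError("manifest carries no genes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    universe = np.array(genes)

    planted: np.ndarray = np.array([], dtype=object)
    if truth is not None and enriched_terms > 0:
        dmp_probes = set(truth.loc[truth["is_dmp"], "probe_id"])
        hits = manifest["IlmnID"].isin(dmp_probes)
        planted = np.array(
            sorted(
                {
                    g
                    for field in manifest.loc[hits, "UCSC_RefGene_Name"]
                    for g in str(field).split(";")
                    if g
                }
            )
        )
    elif enriched_terms > 0:
        raise ValueError("ground truth required to seed enriched terms")

    sets: dict[str, tuple[str, list[str]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(10, min(50, len(universe)) + 1))
        if t < enriched_terms and len(planted):
            k_planted = min(int(round(planted_member_fraction * size)), len(planted))
            members = set(rng.choice(planted, size=k_planted, replace=False))
            rest = universe[~np.isin(universe, list(members))]
            extra = min(size - len(members), len(rest))
            if extra > 0:
                members |= set(rng.choice(rest, size=extra, replace=False))
            desc = "planted enriched set"
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
            desc = "random set"
        sets[f"T{t + 1:04d}"] = (desc, sorted(members))
    if path is not None:
        write_gmt(sets, path)
    return sets


def split_by_dataset(
    beta: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Split a beta matrix and sheet into per-dataset blocks (for merge tests)."""
    matrices, sheets = [], []
    for ds in sheet["dataset_id"].unique():
        sub = sheet[sheet["dataset_id"] == ds].reset_index(drop=True)
        matrices.append(beta[list(sub["sample_id"])])
        sheets.append(sub)
    return matrices, sheets
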