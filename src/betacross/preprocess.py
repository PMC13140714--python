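"""Dataset merging, missingness filtering and beta -> M transformation.

The merge intersects probe sets across studies (order taken from the
first input), concatenates sample columns, and keeps the sample sheet
aligned with the matrix columns. Probes with *more than* a given
fraction of missing values across samples (default 80%) are removed;
the boundary itself is retained. Beta values are mapped to M values
with the base-2 logit after clamping into [epsilon, 1 - epsilon] so
that boundary betas stay finite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class MergeError(ValueError):
    """Raised when input matrices cannot be merged consistently."""


def merge_datasets(
    matrices: list[pd.DataFrame], sheets: list[pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge beta matrices on common probes and concatenate their samples.

    Parameters
    ----------
    matrices
        Probe-by-sample beta matrices; probe order of the first input is
        preserved in the output.
    sheets
        Sample sheets aligned one-to-one with ``matrices``.

    Returns
    -------
    (beta, sheet)
        The merged matrix over the probe intersection and the row-bound
        sample sheet, columns in input order.
    """
    if len(matrices) == 0:
        raise MergeError("need at least one matrix")
    if len(matrices) != len(sheets):
        raise MergeError("matrices and sheets must align one-to-one")

    common = matrices[0].index
    for m in matrices[1:]:
        common = common[common.isin(m.index)]
    if len(common) == 0:
        raise MergeError("probe intersection across datasets is empty")

    all_samples = pd.concat([s["sample_id"] for s in sheets], ignore_index=True)
    dup = all_samples[all_samples.duplicated()]
    if len(dup):
        raise MergeError(f"duplicate sample ids across datasets: {sorted(set(dup))}")

    merged = pd.concat([m.loc[common] for m in matrices], axis=1)
    sheet = pd.concat(sheets, ignore_index=True)
    if list(merged.columns) != list(sheet["sample_id"]):
        raise MergeError("sample sheet rows do not match matrix columns")
    return merged, sheet


def filter_missing(
    matrix: pd.DataFrame, max_missing_fraction: float = 0.8
) -> tuple[pd.DataFrame, int]:
    """Drop probes whose missing fraction exceeds ``max_missing_fraction``.

    A probe at exactly the boundary is retained (removal requires
    strictly more missingness). Returns the filtered matrix and the
    number of removed probes.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError(f"max_missing_fraction must lie in [0, 1], got {max_missing_fraction}")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("matrix must be nonempty")
    missing_frac = matrix.isna().mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    removed = int((~keep).sum())
    logger.info("filter_missing: removed %d of %d probes", removed, matrix.shape[0])
    return matrix.loc[keep], removed


def beta_to_m(matrix: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """Base-2 logit transform: M = log2(beta / (1 - beta)).

    Betas are clamped into [epsilon, 1 - epsilon] first; missing values
    stay missing.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    clipped = matrix.clip(lower=epsilon, upper=1.0 - epsilon)
    with np.errstate(invalid="ignore"):
        m = np.log2(clipped / (1.0 - clipped))
    return m


def m_to_beta(matrix: pd.DataFrame | np.ndarray):
    """Inverse of :func:`beta_to_m` (without the clamp): beta = 2^M / (2^M + 1)."""
    p = np.power(2.0, matrix)
    return p / (p + 1.0)
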