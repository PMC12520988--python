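"""Raw table to analysis-ready matrix.

log2 transform + contaminant removal, group-validity filtering, median
normalization, selective left-censored imputation (Perseus-style downshifted
per-sample normal draws) and replicate-level QC summaries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Replicate-level quality metrics.

    ``cv`` holds per-protein coefficients of variation (%) on the linear
    intensity scale, one column per replicate group; ``median_cv`` the group
    medians; ``completeness`` the fraction of proteins with zero missing
    values; ``n_quantified`` the per-sample count of observed proteins.
    """

    cv: pd.DataFrame
    median_cv: pd.Series
    completeness: float
    n_quantified: pd.Series

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must lie in [0, 1]")


def _as_group_series(matrix: IntensityMatrix, groups) -> pd.Series:
    s = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    missing = matrix.sample_ids.difference(s.index)
    if len(missing):
        raise ValueError(f"samples without group assignment: {list(missing)}")
    return s.reindex(matrix.sample_ids)


def log2_and_clean(matrix: IntensityMatrix, contaminant_prefixes=(),
                   contaminant_patterns=()) -> IntensityMatrix:
    """log2-transform a raw matrix and drop contaminant rows.

    Rows whose protein id starts with any prefix or matches any regex are
    removed.  Non-positive observed intensities cannot be logged and raise.
    """
    if matrix.scale != "raw":
        raise ValueError("matrix is already log2-scaled")
    arr = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(arr)
    if (arr[observed] <= 0).any():
        raise ValueError("non-positive intensity cannot be log2-transformed")
    values = np.log2(matrix.values)
    keep = np.ones(len(values), dtype=bool)
    for i, pid in enumerate(values.index):
        pid = str(pid)
        if any(pid.startswith(p) for p in contaminant_prefixes):
            keep[i] = False
        elif any(re.search(pat, pid) for pat in contaminant_patterns):
            keep[i] = False
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d contaminant rows", n_removed)
    return IntensityMatrix(values.loc[keep], scale="log2", provenance=matrix.provenance)


def _valid_counts(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Observed-value count per protein (rows) and group (columns)."""
    return values.notna().T.groupby(groups).sum().T


def filter_by_group_validity(matrix: IntensityMatrix, groups, min_valid: int) -> IntensityMatrix:
    """Keep proteins with >= min_valid observed values in at least one group."""
    groups = _as_group_series(matrix, groups)
    if min_valid > groups.value_counts().max():
        logger.warning("min_valid=%d exceeds the largest group; all proteins removed", min_valid)
    counts = _valid_counts(matrix.values, groups)
    keep = (counts >= min_valid).any(axis=1)
    return matrix.copy_with(matrix.values.loc[keep])


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Shift every sample so its observed median equals the grand median.

    The anchor is the median of the pre-normalization sample medians, so the
    absolute intensity scale (needed for the variance trend) is retained and
    within-sample differences are untouched.
    """
    if matrix.scale != "log2":
        raise ValueError("median normalization expects log2 scale")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"sample(s) with zero observed values: {empty}")
    target = float(medians.median())
    return matrix.copy_with(matrix.values.sub(medians - target, axis=1))


def impute_left_censored(matrix: IntensityMatrix, groups=None, min_valid: int | None = None,
                         downshift: float = 1.8, width: float = 0.3,
                         mode: str = "selective", seed: int = 0) -> IntensityMatrix:
    """Fill missing cells with draws from the lower tail of each sample.

    Imputed values for sample s are drawn from
    ``Normal(m_s - downshift * sd_s, (width * sd_s)^2)`` where ``m_s`` and
    ``sd_s`` are the mean and SD of that sample's observed log2 intensities.

    mode="all" imputes every missing cell.  mode="selective" imputes a
    protein's missing cells only when at least one group reaches
    ``min_valid`` observed values for it (cells in under-observed groups are
    filled from the tail; sporadic holes inside passing groups are filled
    too, so complete-matrix consumers can run).
    """
    if matrix.scale != "log2":
        raise ValueError("imputation expects log2 scale")
    if mode not in ("selective", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    values = matrix.values.copy()
    missing = values.isna()
    if not missing.to_numpy().any():
        return matrix.copy_with(values)

    if mode == "selective":
        if groups is None or min_valid is None:
            raise ValueError("selective mode needs groups and min_valid")
        gseries = _as_group_series(matrix, groups)
        counts = _valid_counts(values, gseries)
        eligible = (counts >= min_valid).any(axis=1)
        n_skipped = int((~eligible & missing.any(axis=1)).sum())
        if n_skipped:
            logger.info("left %d proteins un-imputed (no group passes min_valid)", n_skipped)
    else:
        eligible = pd.Series(True, index=values.index)

    obs_mean = values.mean(axis=0, skipna=True)
    obs_sd = values.std(axis=0, ddof=1, skipna=True)
    n_obs = values.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = list(values.columns[n_obs < 2])
        raise ValueError(f"sample(s) with <2 observed values, SD undefined: {bad}")

    rng = np.random.default_rng(seed)
    for sample in values.columns:  # fixed column order keeps draws reproducible
        mask = missing[sample] & eligible
        k = int(mask.sum())
        if k == 0:
            continue
        loc = obs_mean[sample] - downshift * obs_sd[sample]
        scale = width * obs_sd[sample]
        values.loc[mask, sample] = rng.normal(loc, scale, size=k)
    return matrix.copy_with(values)


def summarize_quality(matrix: IntensityMatrix, replicate_groups) -> QCReport:
    """CV (%) per protein within each replicate group, plus completeness.

    CVs are computed on linear-scale intensities (2**log2) as 100*sd/mean.
    Groups of size 1 are excluded with a warning.
    """
    groups = _as_group_series(matrix, replicate_groups)
    linear = np.power(2.0, matrix.values) if matrix.scale == "log2" else matrix.values
    cv_cols = {}
    for g, cols in groups.groupby(groups).groups.items():
        if len(cols) < 2:
            logger.warning("replicate group %r has a single sample; excluded from CV", g)
            continue
        sub = linear[list(cols)]
        cv_cols[g] = 100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    if not cv_cols:
        raise ValueError("no replicate group with >=2 samples")
    cv = pd.DataFrame(cv_cols)
    completeness = float(matrix.values.notna().all(axis=1).mean())
    return QCReport(cv=cv, median_cv=cv.median(axis=0, skipna=True),
                    completeness=completeness,
                    n_quantified=matrix.values.notna().sum(axis=0))
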