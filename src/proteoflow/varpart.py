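"""Per-protein variance decomposition into experimental factors.

For each protein the model is an intercept plus one random effect per
factor (individual, workflow, fixation, ...) and a residual:

    y = mu + sum_f u_f + eps,   u_f ~ N(0, sigma2_f I),  eps ~ N(0, sigma2_e I)

fitted by REML over the variance ratios gamma_f = sigma2_f / sigma2_e
(bounded low-dimensional optimization; the residual variance is profiled
out analytically).  The reported quantity per protein is the fraction of
total variance attributable to each factor,
fraction_f = sigma2_f / (sum_f sigma2_f + sigma2_e).  Negative component
estimates are truncated at the zero boundary.  On balanced one-factor
designs the interior REML solution coincides with the closed-form ANOVA
(method-of-moments) estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import IntensityMatrix, SampleMetadata

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_FAILED = "failed"
STATUS_SKIPPED = "skipped"


@dataclass
class VarianceFractions:
    """Per-protein variance fractions and fit status.

    ``fractions`` has one column per factor plus ``residual``; rows whose
    ``status`` is not ``ok`` hold NaN (never silent zeros).
    """

    fractions: pd.DataFrame
    status: pd.Series
    factors: list[str]

    def converged(self) -> pd.DataFrame:
        return self.fractions.loc[self.status == STATUS_OK]


def _factor_incidence(labels: np.ndarray) -> np.ndarray:
    """n x q 0/1 incidence matrix of a factor's levels."""
    levels, codes = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


def _check_factors(meta: pd.DataFrame, factors) -> None:
    parts = {}
    for f in factors:
        if f not in meta.columns:
            raise ValueError(f"metadata has no factor column {f!r}")
        labels = meta[f].astype(str).to_numpy()
        if len(np.unique(labels)) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        parts[f] = pd.factorize(labels)[0]
    names = list(parts)
    for i, f in enumerate(names):
        for g in names[i + 1:]:
            a, b = parts[f], parts[g]
            # identical partitions => perfectly confounded random effects
            a_nests_b = all(len(np.unique(b[a == lev])) == 1 for lev in np.unique(a))
            b_nests_a = all(len(np.unique(a[b == lev])) == 1 for lev in np.unique(b))
            if a_nests_b and b_nests_a:
                raise ValueError(f"factors {f!r} and {g!r} define identical groupings")


def _reml_neg_loglik(log_gamma: np.ndarray, y: np.ndarray, ZZt: list[np.ndarray]) -> float:
    n = len(y)
    V = np.eye(n)
    for g, M in zip(np.exp(log_gamma), ZZt):
        V = V + g * M
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(n)
    Vi_one = np.linalg.solve(V, ones)
    xtvx = float(ones @ Vi_one)
    beta = float(ones @ np.linalg.solve(V, y)) / xtvx
    r = y - beta
    rss = float(r @ np.linalg.solve(V, r))
    if rss <= 0 or xtvx <= 0:
        return np.inf
    return logdet_v + np.log(xtvx) + (n - 1) * np.log(rss / (n - 1))


def _fit_one(y: np.ndarray, ZZt: list[np.ndarray], n_factors: int
             ) -> tuple[np.ndarray, float, bool]:
    """REML variance components for one protein.

    Returns (sigma2 per factor, sigma2_residual, converged).  Optimizes over
    log variance ratios; a boundary component is detected by a very small
    fitted ratio and truncated to exactly zero.
    """
    n = len(y)
    lo, hi = np.log(1e-8), np.log(1e8)
    if n_factors == 1:
        res = optimize.minimize_scalar(
            lambda t: _reml_neg_loglik(np.array([t]), y, ZZt),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
        theta = np.array([res.x])
        ok = res.success if res.success is not None else True
    else:
        best = None
        for start in (np.zeros(n_factors), np.full(n_factors, np.log(0.1)),
                      np.full(n_factors, np.log(10.0))):
            res = optimize.minimize(
                _reml_neg_loglik, start, args=(y, ZZt),
                method="Nelder-Mead",
                bounds=[(lo, hi)] * n_factors,
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        ok = bool(best.success)
    gamma = np.exp(theta)
    gamma[gamma < 1e-6] = 0.0       # boundary truncation
    V = np.eye(n)
    for g, M in zip(gamma, ZZt):
        V = V + g * M
    ones = np.ones(n)
    Vi_one = np.linalg.solve(V, ones)
    beta = float(ones @ np.linalg.solve(V, y)) / float(ones @ Vi_one)
    r = y - beta
    s2e = float(r @ np.linalg.solve(V, r)) / (n - 1)
    return gamma * s2e, s2e, ok


def decompose_variance(matrix: IntensityMatrix, metadata: SampleMetadata,
                       factors) -> VarianceFractions:
    """REML variance fractions per protein for the named metadata factors.

    Proteins with too few observations (fewer than number of factors + 2),
    or zero total variance, are flagged rather than fitted.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("need at least one factor")
    meta = metadata.table.loc[matrix.sample_ids]
    _check_factors(meta, factors)
    labels = {f: meta[f].astype(str).to_numpy() for f in factors}

    Y = matrix.values.to_numpy(dtype=float)
    obs_all = ~np.isnan(Y)
    cols = factors + ["residual"]
    frac = np.full((Y.shape[0], len(cols)), np.nan)
    status = np.array([STATUS_SKIPPED] * Y.shape[0], dtype=object)

    zzt_cache: dict[bytes, list[np.ndarray]] = {}
    for i in range(Y.shape[0]):
        mask = obs_all[i]
        n_obs = int(mask.sum())
        if n_obs < len(factors) + 2:
            continue
        y = Y[i, mask]
        if np.ptp(y) == 0.0:
            status[i] = STATUS_DEGENERATE
            continue
        key = mask.tobytes()
        if key not in zzt_cache:
            mats = []
            for f in factors:
                Z = _factor_incidence(labels[f][mask])
                mats.append(Z @ Z.T)
            zzt_cache[key] = mats
        try:
            sig2, s2e, ok = _fit_one(y, zzt_cache[key], len(factors))
        except (np.linalg.LinAlgError, ValueError):
            status[i] = STATUS_FAILED
            continue
        total = sig2.sum() + s2e
        if not np.isfinite(total) or total <= 0 or not ok:
            status[i] = STATUS_FAILED
            continue
        frac[i, :-1] = sig2 / total
        frac[i, -1] = s2e / total
        status[i] = STATUS_OK

    fractions = pd.DataFrame(frac, index=matrix.protein_ids, columns=cols)
    return VarianceFractions(fractions, pd.Series(status, index=matrix.protein_ids),
                             factors)


def summarize_fractions(vf: VarianceFractions) -> pd.DataFrame:
    """Median and quartiles of each factor's fraction over converged proteins."""
    conv = vf.converged()
    if len(conv) == 0:
        raise ValueError("no converged variance-partition fits to summarize")
    rows = {}
    for col in conv.columns:
        q1, med, q3 = np.percentile(conv[col].to_numpy(), [25, 50, 75])
        rows[col] = {"median": med, "q1": q1, "q3": q3, "n": len(conv)}
    return pd.DataFrame(rows).T
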