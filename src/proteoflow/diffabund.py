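"""Differential protein abundance with empirical-Bayes variance moderation.

Per-protein ordinary (or, with a block correlation, generalized) least
squares on log2 intensities, followed by shrinkage of the residual
variances toward a prior — either a constant or a smooth trend over average
intensity — estimated by moment matching of the log residual variances
(digamma/trigamma inversion).  The moderated t-statistic for protein g is

    t_g = beta_g / sqrt(s2_post_g * v_g),
    s2_post_g = (d0 * s2_prior(A_g) + d_g * s2_g) / (d0 + d_g)

with d0 + d_g degrees of freedom.  Two-sided p-values are controlled by
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix, SampleMetadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Design matrix plus bookkeeping for a two-group contrast."""

    matrix: np.ndarray           # n_samples x p
    columns: list[str]
    sample_ids: list[str]
    coef_name: str               # column holding the contrast log2FC
    block: np.ndarray | None = None   # integer block codes aligned to samples

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design(metadata: SampleMetadata, condition: str = "group",
                 contrast: tuple[str, str] | None = None,
                 covariates=(), batch: str | None = None,
                 block: str | None = None) -> Design:
    """Intercept + contrast indicator (+ covariates, batch dummies).

    ``contrast=(A, B)`` makes the contrast coefficient the A-minus-B log2
    fold change.  Samples outside the two levels, or with missing covariate
    values, are dropped (complete-case, with a logged count).
    """
    table = metadata.table
    cond = table[condition].astype(str)
    if contrast is None:
        levels = list(dict.fromkeys(cond))
        if len(levels) != 2:
            raise ValueError(f"condition {condition!r} has {len(levels)} levels; "
                             "pass contrast=(A, B)")
        contrast = (levels[0], levels[1])
    a, b = contrast
    keep = cond.isin([a, b])
    sub = table.loc[keep]
    for cov in covariates:
        before = len(sub)
        sub = sub.loc[sub[cov].notna()]
        if len(sub) < before:
            logger.info("dropped %d samples with missing covariate %r", before - len(sub), cov)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(sub))}
    coef_name = f"{a}-{b}"
    cols[coef_name] = (sub[condition].astype(str) == a).to_numpy(dtype=float)
    for cov in covariates:
        series = sub[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols[cov] = series.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
    if batch is not None:
        dummies = pd.get_dummies(sub[batch].astype(str), prefix=batch, drop_first=True)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    blocks = None
    if block is not None:
        codes, _ = pd.factorize(sub[block].astype(str))
        blocks = codes
    return Design(X, names, list(sub.index), coef_name, blocks)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# per-protein linear fits
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Per-protein OLS/GLS summaries feeding the moderation step."""

    coefficients: pd.DataFrame      # proteins x design columns
    stdev_unscaled: pd.Series       # sqrt of the unscaled contrast-coef variance
    sigma2: pd.Series               # residual variance s_g^2
    df_residual: pd.Series          # d_g
    amean: pd.Series                # A_g, mean observed log2 intensity
    coef_name: str
    excluded: list[str] = field(default_factory=list)


def _block_eigens(blocks: np.ndarray):
    """Eigendecomposition of the same-block indicator matrix B.

    The compound-symmetric correlation V(rho) = (1-rho) I + rho B shares B's
    eigenvectors for every rho, so GLS for any rho is a diagonal reweighting
    in this fixed basis.
    """
    B = (blocks[:, None] == blocks[None, :]).astype(float)
    lam, Q = np.linalg.eigh(B)
    return lam, Q


def _v_eigvals(lam: np.ndarray, rho: float) -> np.ndarray:
    return (1.0 - rho) + rho * lam


def fit_linear_models(matrix: IntensityMatrix, design: Design,
                      correlation: float | None = None) -> LinearFit:
    """OLS (or compound-symmetric GLS when ``correlation`` is given) per protein.

    Complete-case per protein: each protein uses its observed samples only
    and needs at least rank+1 of them; proteins below that are excluded and
    reported with missing statistics.
    """
    if matrix.scale != "log2":
        raise ValueError("differential testing expects log2 intensities")
    Y = matrix.values[design.sample_ids].to_numpy(dtype=float)
    X = design.matrix
    p = X.shape[1]
    ci = design.columns.index(design.coef_name)
    n_prot = Y.shape[0]

    coeffs = np.full((n_prot, p), np.nan)
    stdev = np.full(n_prot, np.nan)
    sigma2 = np.full(n_prot, np.nan)
    dfres = np.full(n_prot, np.nan)
    amean = np.full(n_prot, np.nan)
    excluded: list[int] = []

    obs = ~np.isnan(Y)
    amean_all = np.where(obs.any(axis=1), np.nanmean(np.where(obs, Y, np.nan), axis=1), np.nan)

    # group proteins by missingness pattern so each pattern is solved once
    patterns: dict[bytes, list[int]] = {}
    for g in range(n_prot):
        patterns.setdefault(obs[g].tobytes(), []).append(g)

    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n_obs = int(mask.sum())
        if n_obs < p + 1:
            excluded.extend(rows)
            continue
        Xs = X[mask]
        if np.linalg.matrix_rank(Xs) < p:
            excluded.extend(rows)
            continue
        Ys = Y[np.ix_(rows, mask)]
        if correlation is not None and design.block is not None:
            lam, Q = _block_eigens(design.block[mask])
            w = 1.0 / np.sqrt(_v_eigvals(lam, correlation))
            Xs = (Q.T @ Xs) * w[:, None]
            Ys = (Q.T @ Ys.T).T * w[None, :]
        XtX_inv = np.linalg.inv(Xs.T @ Xs)
        beta = Ys @ (XtX_inv @ Xs.T).T            # rows x p
        resid = Ys - beta @ Xs.T
        rss = np.einsum("ij,ij->i", resid, resid)
        d = n_obs - p
        coeffs[rows] = beta
        sigma2[rows] = rss / d
        dfres[rows] = d
        stdev[rows] = np.sqrt(XtX_inv[ci, ci])
        amean[rows] = amean_all[rows]

    if excluded:
        logger.info("excluded %d proteins with insufficient observations", len(excluded))
    idx = matrix.protein_ids
    return LinearFit(
        coefficients=pd.DataFrame(coeffs, index=idx, columns=design.columns),
        stdev_unscaled=pd.Series(stdev, index=idx),
        sigma2=pd.Series(sigma2, index=idx),
        df_residual=pd.Series(dfres, index=idx),
        amean=pd.Series(amean, index=idx),
        coef_name=design.coef_name,
        excluded=[str(idx[g]) for g in excluded],
    )


# ---------------------------------------------------------------------------
# consensus intra-block correlation
# ---------------------------------------------------------------------------

def estimate_consensus_correlation(matrix: IntensityMatrix, design: Design,
                                   rho_bound: float = 0.99) -> float:
    """Consensus within-block correlation across proteins.

    For each protein, the within-block correlation of a one-random-effect
    model is estimated by REML (bounded 1-D optimization of the profiled
    likelihood over rho); the consensus is tanh of the 15%-trimmed mean of
    atanh(rho_g).
    """
    if design.block is None:
        raise ValueError("design carries no block assignment")
    blocks = design.block
    sizes = np.bincount(blocks)
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >=2 blocks with >=2 samples to estimate correlation")
    Y = matrix.values[design.sample_ids].to_numpy(dtype=float)
    X = design.matrix
    p = X.shape[1]

    obs = ~np.isnan(Y)
    rho_hat: list[float] = []
    cache: dict[bytes, tuple] = {}
    for g in range(Y.shape[0]):
        mask = obs[g]
        n_obs = int(mask.sum())
        if n_obs < p + 2:
            continue
        sub_blocks = blocks[mask]
        if (np.bincount(sub_blocks) >= 2).sum() < 2:
            continue
        key = mask.tobytes()
        if key not in cache:
            lam, Q = _block_eigens(sub_blocks)
            cache[key] = (lam, Q, Q.T @ X[mask])
        lam, Q, Xt = cache[key]
        if np.linalg.matrix_rank(Xt) < p:
            continue
        y = Q.T @ Y[g, mask]

        def neg_reml(rho: float) -> float:
            w = _v_eigvals(lam, rho)
            if (w <= 1e-10).any():
                return np.inf
            sw = 1.0 / np.sqrt(w)
            Xw = Xt * sw[:, None]
            yw = y * sw
            XtXw = Xw.T @ Xw
            try:
                beta = np.linalg.solve(XtXw, Xw.T @ yw)
            except np.linalg.LinAlgError:
                return np.inf
            r = yw - Xw @ beta
            rss = float(r @ r)
            if rss <= 0:
                return np.inf
            sign, logdet_x = np.linalg.slogdet(XtXw)
            if sign <= 0:
                return np.inf
            return (np.log(w).sum() + logdet_x
                    + (len(y) - p) * np.log(rss / (len(y) - p)))

        res = optimize.minimize_scalar(neg_reml, bounds=(-rho_bound, rho_bound),
                                       method="bounded", options={"xatol": 1e-4})
        rho_hat.append(float(res.x))
    if not rho_hat:
        raise ValueError("no protein allowed a within-block correlation estimate")
    z = np.arctanh(np.clip(rho_hat, -0.999, 0.999))
    return float(np.tanh(stats.trim_mean(z, 0.15)))


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModerationHyper:
    """Estimated prior: degrees of freedom d0 and prior variance s2_prior
    (a per-protein array when a trend over average intensity is fitted)."""

    df_prior: float
    s2_prior: np.ndarray | float
    trend: bool


@dataclass
class DEResult:
    """Moderated differential-abundance table plus the prior used."""

    table: pd.DataFrame   # logFC, AveExpr, t, P.Value, adj.P.Val, df_total
    hyper: ModerationHyper

    @property
    def t(self) -> pd.Series:
        return self.table["t"]


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(sigma2: np.ndarray, df: np.ndarray, amean: np.ndarray | None = None,
                      trend: bool = False, span: float = 0.5) -> ModerationHyper:
    """Estimate (d0, s2_prior) by moment matching of log residual variances.

    With ``trend=True`` the prior variance is a locally weighted regression
    of log s2 on average intensity; otherwise a scalar.
    """
    ok = np.isfinite(sigma2) & np.isfinite(df) & (df > 0)
    s2 = sigma2[ok]
    d = df[ok]
    if len(s2) < 2:
        raise ValueError("need >=2 proteins with positive residual df")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; moderation degenerate")
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if trend:
        if amean is None:
            raise ValueError("trend=True needs average intensities")
        a = amean[ok]
        emean_ok = sm_lowess(e, a, frac=span, it=3, return_sorted=False)
        # extend the curve to excluded proteins by nearest observed intensity
        order = np.argsort(a)
        emean_full = np.interp(np.where(np.isfinite(amean), amean, np.nanmedian(a)),
                               a[order], emean_ok[order])
        resid_e = e - emean_ok
        evar = float(np.sum(resid_e ** 2) / (len(e) - 1))
        s2_prior_arr = None  # filled below once d0 known
    else:
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1))
    evar -= float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        offset = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        s2_prior = np.exp(emean_full + offset) if trend else float(np.exp(emean + offset))
    else:
        # no excess spread in the log variances: infinite prior df; the prior
        # is the plain mean of the variances (or the trend curve)
        d0 = np.inf
        s2_prior = np.exp(emean_full) if trend else float(np.mean(s2))
    return ModerationHyper(float(d0), s2_prior, trend)


def moderate_statistics(fit: LinearFit, trend: bool = True,
                        prior_df: float | None = None,
                        span: float = 0.5) -> DEResult:
    """Moderated t-statistics, two-sided p-values and BH adjustment.

    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t,
    ``numpy.inf`` the fully shrunk limit t = beta / sqrt(s2_prior * v)).
    """
    sigma2 = fit.sigma2.to_numpy()
    df = fit.df_residual.to_numpy()
    amean = fit.amean.to_numpy()
    hyper = squeeze_variances(sigma2, df, amean, trend=trend, span=span)
    if prior_df is not None:
        hyper = ModerationHyper(float(prior_df), hyper.s2_prior, hyper.trend)
    d0 = hyper.df_prior
    s2_prior = np.asarray(hyper.s2_prior) if hyper.trend else hyper.s2_prior

    df_pooled = float(np.nansum(df))  # cap: no protein can exceed the pooled df
    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            s2_post = np.broadcast_to(np.asarray(s2_prior, dtype=float),
                                      sigma2.shape).astype(float)
            df_total = np.full_like(sigma2, df_pooled)
        elif d0 == 0:
            s2_post = sigma2.copy()
            df_total = df.copy()
        else:
            s2_post = (d0 * s2_prior + df * sigma2) / (d0 + df)
            df_total = np.minimum(d0 + df, df_pooled)
        lfc = fit.coefficients[fit.coef_name].to_numpy()
        tstat = lfc / (np.sqrt(s2_post) * fit.stdev_unscaled.to_numpy())
        pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    padj = np.full_like(pval, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = adjust_bh(pval[tested])
    table = pd.DataFrame({
        "logFC": lfc, "AveExpr": amean, "t": tstat,
        "P.Value": pval, "adj.P.Val": padj, "df_total": df_total,
    }, index=fit.coefficients.index)
    return DEResult(table, hyper)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_tstatistics(result_a: DEResult, result_b: DEResult) -> float:
    """Pearson correlation of moderated t over the shared, finite proteins."""
    shared = result_a.table.index.intersection(result_b.table.index)
    ta = result_a.table.loc[shared, "t"]
    tb = result_b.table.loc[shared, "t"]
    ok = ta.notna() & tb.notna()
    if ok.sum() < 3:
        raise ValueError("need >=3 shared proteins with finite statistics")
    return float(np.corrcoef(ta[ok], tb[ok])[0, 1])
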