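"""Unsupervised and supervised descriptive analyses of a proteome matrix.

Samples are the observations and proteins the variables: PCA by singular
value decomposition of the centered matrix, Ward-D2 hierarchical clustering
on Euclidean distances, pairwise-complete Pearson correlation, and PLS-DA
(NIPALS partial least squares against a one-hot group response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cross_decomposition import PLSRegression

from .io import IntensityMatrix


@dataclass
class PcaResult:
    """Sample scores, protein loadings and percent variance per component."""

    scores: pd.DataFrame          # samples x PC
    loadings: pd.DataFrame        # proteins x PC
    explained_pct: pd.Series      # percent of total variance per PC

    def __post_init__(self) -> None:
        v = self.explained_pct.to_numpy()
        if (np.diff(v) > 1e-9).any() or (v < -1e-9).any() or v.sum() > 100 + 1e-6:
            raise ValueError("variance percentages must be non-increasing, >=0, sum <=100")


@dataclass
class DendrogramSpec:
    """Agglomeration sequence of Ward-D2 clustering.

    ``linkage`` is a scipy linkage matrix over samples; ``merges`` lists
    (left, right, height, size) per step with non-decreasing heights.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def merges(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage, columns=["left", "right", "height", "size"])

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _complete_samples_by_proteins(matrix: IntensityMatrix) -> np.ndarray:
    values = matrix.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix has missing cells; impute or take complete cases first")
    return values.T  # samples x proteins


def pca(matrix: IntensityMatrix, center: bool = True, scale: bool = False) -> PcaResult:
    """PCA of samples over protein variables via SVD.

    Scores are the centered (optionally unit-scaled) data projected on the
    orthonormal loadings; percent variance comes from the squared singular
    values.
    """
    X = _complete_samples_by_proteins(matrix)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs >=2 samples")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n, X.shape[1])
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = U[:, :k] * s[:k]
    total = float((s ** 2).sum())
    pct = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comps),
        loadings=pd.DataFrame(Vt[:k].T, index=matrix.protein_ids, columns=comps),
        explained_pct=pd.Series(pct, index=comps),
    )


def hierarchical_cluster(matrix: IntensityMatrix, linkage: str = "ward") -> DendrogramSpec:
    """Ward-D2 agglomerative clustering of samples on Euclidean distances."""
    X = _complete_samples_by_proteins(matrix)
    if X.shape[0] < 2:
        raise ValueError("clustering needs >=2 samples")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    return DendrogramSpec(Z, list(matrix.sample_ids))


def correlation_matrix(matrix: IntensityMatrix, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between samples.

    Pairs sharing fewer than ``min_periods`` observed proteins are NaN
    (flagged undefined); the diagonal is exactly 1 for non-empty samples.
    """
    corr = matrix.values.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


@dataclass
class PlsdaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # proteins x components
    centroids: pd.DataFrame     # groups x components
    groups: pd.Series

    def separation_ratio(self, component: str = "C1") -> float:
        """Between-group over within-group variance of one score column."""
        s = self.scores[component]
        overall = s.to_numpy().var(ddof=1)
        within = float(np.mean([s[self.groups == g].var(ddof=1)
                                for g in self.groups.unique()
                                if (self.groups == g).sum() > 1]))
        return overall / within if within > 0 else np.inf


def plsda(matrix: IntensityMatrix, groups, n_components: int = 2,
          scale: bool = True) -> PlsdaResult:
    """Partial least squares discriminant analysis of samples.

    The response is the one-hot encoding of the group labels; predictors
    are centered (and unit-scaled when ``scale``); components come from
    NIPALS sequential extraction with deflation.
    """
    X = _complete_samples_by_proteins(matrix)
    g = pd.Series(groups)
    g = g.reindex(matrix.sample_ids)
    if g.isna().any():
        raise ValueError("every sample needs a group label")
    levels = list(dict.fromkeys(g))
    if len(levels) < 2:
        raise ValueError("PLS-DA needs >=2 groups")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0, keepdims=True))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    Y = pd.get_dummies(g).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=scale)
    pls.fit(X, Y)
    comps = [f"C{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(pls.x_scores_, index=matrix.sample_ids, columns=comps)
    loadings = pd.DataFrame(pls.x_loadings_, index=matrix.protein_ids, columns=comps)
    centroids = scores.groupby(g).mean()
    return PlsdaResult(scores, loadings, centroids, g)
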