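"""Exploratory chemometric screens: PCA, PLS-DA and hierarchical clustering.

These reproduce the unsupervised / lightly supervised first look that
typically precedes classifier building on metabolic fingerprints.  In the
emulated study none of these screens separates disease grades cleanly —
that failure motivates the regularized-regression modeling stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression

from .fingerprint import FingerprintMatrix

__all__ = ["OrdinationResult", "pca", "plsda", "hier_cluster_samples"]


@dataclass
class OrdinationResult:
    """Scores, loadings and per-component explained-variance fractions.

    For PCA, ``explained_variance`` is the fraction of (centered, optionally
    scaled) X variance per component, non-increasing.  For PLS-DA it is the
    fraction of one-hot label variance captured per component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _sign_fix(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic orientation: each loading's largest-|entry| is positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1


def _as_xy(matrix):
    if isinstance(matrix, FingerprintMatrix):
        return matrix.values, [f"{m:.4f}" for m in matrix.feature_mz], list(matrix.sample_ids)
    x = np.asarray(matrix, dtype=float)
    return x, [f"f{j}" for j in range(x.shape[1])], [f"s{i}" for i in range(x.shape[0])]


def pca(matrix, n_components: int = 2, scale: str = "unit-variance") -> OrdinationResult:
    """Principal component analysis via SVD of the centered (scaled) matrix."""
    x, feat_names, sample_names = _as_xy(matrix)
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n_samples-1, n_features) = {min(n - 1, p)}")
    xc = x - x.mean(axis=0)
    if scale == "unit-variance":
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature(s) with unit-variance scaling")
        xc = xc / sd
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T.copy()
    _sign_fix(scores, loadings)
    expl = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp = [f"PC{a + 1}" for a in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=sample_names, columns=comp),
        loadings=pd.DataFrame(loadings, index=feat_names, columns=comp),
        explained_variance=expl,
    )


def plsda(matrix, labels, n_components: int = 2) -> OrdinationResult:
    """Partial least squares discriminant analysis (NIPALS PLS2, one-hot Y)."""
    x, feat_names, sample_names = _as_xy(matrix)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA requires at least 2 classes")
    y = (labels[:, None] == classes[None, :]).astype(float)

    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(x, y)
    scores = np.asarray(pls.x_scores_)
    loadings = np.asarray(pls.x_loadings_).copy()
    _sign_fix(scores, loadings)

    # fraction of (centered/scaled) label variance captured by each component
    y0 = (y - y.mean(axis=0))
    sd = y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    y0 = y0 / sd
    tot = float((y0**2).sum())
    expl = np.zeros(n_components)
    for a in range(n_components):
        t = scores[:, a]
        denom = float(t @ t)
        if denom > 0 and tot > 0:
            q = y0.T @ t / denom
            expl[a] = float(denom * (q @ q)) / tot
    comp = [f"LV{a + 1}" for a in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=sample_names, columns=comp),
        loadings=pd.DataFrame(loadings, index=feat_names, columns=comp),
        explained_variance=expl,
    )


def hier_cluster_samples(matrix, linkage_method: str = "ward", k: int = 2) -> dict:
    """Agglomerative clustering of samples on z-scored features.

    Returns a mapping sample_id -> cluster id (1..k).  Distances are
    Euclidean; constant features are left unscaled (contribution zero).
    """
    x, _, sample_names = _as_xy(matrix)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError("k must be <= number of samples")
    if linkage_method not in ("ward", "average"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    sd = x.std(axis=0, ddof=1)
    mean = x.mean(axis=0)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if x.shape[0] == 1:
        return {sample_names[0]: 1}
    tree = linkage(z, method=linkage_method)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return dict(zip(sample_names, (int(c) for c in labels)))
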