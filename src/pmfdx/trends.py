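"""Trend clustering of features across the three clinical groups.

Each feature's mean intensity over {simple HM, MMD 2-3, MMD 4} is z-scored
within the feature (shape, not amplitude) and the resulting 3-point profiles
are k-means clustered into trend archetypes, e.g. consistent up/down
regulation in both disease groups versus changes specific to MMD 4 or to
MMD 2-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import FingerprintMatrix
from .synthetic import GROUP_ORDER

__all__ = ["TrendProfile", "TrendClusters", "compute_trend_profiles", "cluster_trends"]


@dataclass
class TrendProfile:
    """One feature's group-mean profile, z-scored across the three groups."""

    feature_mz: float
    raw_means: np.ndarray
    profile: np.ndarray
    flat: bool = False


@dataclass
class TrendClusters:
    assignments: dict           # feature_mz -> cluster id (1..k)
    centroids: np.ndarray       # k x 3, rows ordered by first-group value descending
    k: int
    inertia: float

    def cluster_members(self, cluster_id: int) -> list:
        return [m for m, c in self.assignments.items() if c == cluster_id]


def compute_trend_profiles(matrix: FingerprintMatrix, group3) -> list:
    """Per-feature group means in the order (simple HM, MMD 2-3, MMD 4), z-scored.

    ``group3`` maps sample_id -> group name.  Profiles with an SD below 1e-12
    across the three means carry the flat flag and a zero profile.
    """
    groups = [group3[s] if not hasattr(group3, "loc") else group3.loc[s] for s in matrix.sample_ids]
    groups = np.asarray(groups)
    masks = []
    for g in GROUP_ORDER:
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} has no samples")
        masks.append(mask)

    profiles = []
    for j, mz in enumerate(matrix.feature_mz):
        col = matrix.values[:, j]
        means = np.array([col[m].mean() for m in masks])
        sd = means.std(ddof=0)
        if sd < 1e-12:
            profiles.append(TrendProfile(float(mz), means, np.zeros(3), flat=True))
        else:
            profiles.append(TrendProfile(float(mz), means, (means - means.mean()) / sd, flat=False))
    return profiles


def _kmeans(x: np.ndarray, k: int, seed: int, n_restarts: int):
    """Seeded k-means (k-means++ inits, Lloyd iterations), best of n_restarts."""
    rng = np.random.default_rng(seed)
    best_inertia = np.inf
    best_labels = best_centers = None
    n = x.shape[0]
    for _ in range(n_restarts):
        # k-means++ seeding
        centers = [x[rng.integers(n)]]
        for _ in range(1, k):
            d2 = np.min(((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1)
            if d2.sum() == 0:
                centers.append(x[rng.integers(n)])
            else:
                centers.append(x[rng.choice(n, p=d2 / d2.sum())])
        centers = np.asarray(centers, dtype=float)
        for _ in range(300):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            labels = d2.argmin(axis=1)
            new_centers = centers.copy()
            for c in range(k):
                pts = x[labels == c]
                if pts.size:
                    new_centers[c] = pts.mean(axis=0)
            if np.allclose(new_centers, centers):
                centers = new_centers
                break
            centers = new_centers
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels, best_centers = inertia, labels, centers
    return best_labels, best_centers, best_inertia


def cluster_trends(profiles: list, k: int = 5, seed: int = 0, n_restarts: int = 50) -> TrendClusters:
    """k-means on z-scored trend profiles with deterministic cluster labeling.

    Flat-flagged features are assigned after clustering, to the centroid
    nearest the zero vector.  Cluster ids 1..k are ordered by the centroid's
    first-group (simple HM) value, descending.
    """
    nonflat = [p for p in profiles if not p.flat]
    if k > len(nonflat):
        raise ValueError(f"k={k} exceeds the {len(nonflat)} non-flat profiles")
    x = np.asarray([p.profile for p in nonflat])
    labels, centers, inertia = _kmeans(x, k, seed, n_restarts)

    order = np.argsort(-centers[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = {p.feature_mz: int(relabel[c]) for p, c in zip(nonflat, labels)}
    flat_cluster = int(relabel[int(np.argmin((centers**2).sum(axis=1)))])
    for p in profiles:
        if p.flat:
            assignments[p.feature_mz] = flat_cluster
    return TrendClusters(assignments=assignments, centroids=centers[order], k=k, inertia=inertia)
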