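"""Biomarker panel selection.

From a fitted full-fingerprint model: rank features by |coefficient|, keep
the top ``max_rank``, drop features without a significant univariate group
difference (two-tailed Welch t-test), then exhaustively evaluate every
combination of the surviving key features up to ``max_size`` by refitting the
logistic regression on the discovery rows.  Each combination is scored by
its stratified cross-validated discovery AUC — in-sample AUC would grow
monotonically with panel size and always select the largest allowed
combination, whereas held-out scoring lets small panels win.  The best
combination (ties: fewer features, then lexicographic m/z) is the panel; a
frozen refit of that panel can then be applied to an external cohort mapped
onto the same feature axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .fingerprint import FingerprintMatrix
from .model import (
    FittedModel,
    HyperGrid,
    RocResult,
    cross_validated_auc,
    evaluate_roc,
    tune_and_fit,
)
from .stats import welch_t_two_tailed

__all__ = ["KeyFeatureSet", "PanelResult", "rank_key_features", "search_panel", "evaluate_panel_external"]


@dataclass
class KeyFeatureSet:
    """Top-coefficient features that also pass the univariate t-test filter.

    ``features`` is ordered by |coefficient| descending (ties: lower m/z);
    each entry is (feature_mz, |coefficient|, t_test_p).
    """

    features: list
    max_rank: int = 30

    @property
    def feature_mz(self) -> np.ndarray:
        return np.asarray([f[0] for f in self.features])

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class PanelResult:
    features: np.ndarray
    discovery_auc: RocResult
    validation_auc: RocResult | None
    search_log: dict
    model: FittedModel
    search_score: float          # winning combination's cross-validated AUC
    best_singleton_auc: float    # best single-feature cross-validated AUC

    def to_json(self, path=None) -> str:
        payload = {
            "features": [f"{m:.4f}" for m in self.features],
            "discovery": json.loads(self.discovery_auc.to_json()),
            "validation": None if self.validation_auc is None else json.loads(self.validation_auc.to_json()),
            "search_log": {str(k): v for k, v in self.search_log.items()},
            "search_score_cv_auc": self.search_score,
            "best_singleton_cv_auc": self.best_singleton_auc,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def rank_key_features(model: FittedModel, matrix: FingerprintMatrix, labels,
                      max_rank: int = 30, alpha: float = 0.05) -> KeyFeatureSet:
    """Select the key features: top |coefficient| ranks minus non-significant ones."""
    if model.feature_mz.size != matrix.n_features or not np.allclose(model.feature_mz, matrix.feature_mz):
        raise ValueError("model was fitted on a different feature axis")
    y = np.asarray(labels).astype(int)
    coefs = np.abs(model.coefficients)
    order = sorted(range(coefs.size), key=lambda j: (-coefs[j], model.feature_mz[j]))
    order = order[:max_rank]
    kept = []
    for j in order:
        col = matrix.values[:, j]
        _, p = welch_t_two_tailed(col[y == 1], col[y == 0])
        if p < alpha:
            kept.append((float(model.feature_mz[j]), float(coefs[j]), float(p)))
    if not kept:
        raise ValueError(
            f"no feature survived: top-{max_rank} coefficient ranks all have Welch p >= {alpha}"
        )
    return KeyFeatureSet(features=kept, max_rank=max_rank)


def _fit_subset(matrix: FingerprintMatrix, y: np.ndarray, feats, grid: HyperGrid) -> FittedModel:
    sub = matrix.subset_features(feats)
    return tune_and_fit(sub, y, grid)


def _score_subset(matrix: FingerprintMatrix, y: np.ndarray, feats, grid: HyperGrid,
                  n_repeats: int) -> float:
    """Repeated cross-validated discovery AUC of the subset, maximized over the grid.

    Averaging over ``n_repeats`` fold assignments shrinks fold-partition noise,
    which otherwise drowns the ~0.01-0.02 AUC margin that separates close
    combinations.
    """
    sub = matrix.subset_features(feats).values
    return max(
        float(np.mean([
            cross_validated_auc(sub, y, pen, strength, grid.n_folds, grid.fold_seed + r)
            for r in range(n_repeats)
        ]))
        for pen, strength in grid.candidates
    )


def search_panel(key: KeyFeatureSet, matrix: FingerprintMatrix, labels,
                 max_size: int = 6, cv: HyperGrid = HyperGrid(penalties=("l2",), strength_grid=(1.0,)),
                 budget: int = 2_000_000, n_repeats: int = 3,
                 validation_matrix: FingerprintMatrix | None = None,
                 validation_labels=None) -> PanelResult:
    """Exhaustive incremental combination search over the key features.

    Every combination of sizes 1..max_size is scored by refitting the LR
    (tuned over ``cv`` restricted to the subset) on the discovery rows and
    taking its repeated cross-validated discovery AUC.  A total-combination
    ``budget`` guards the exponential search space.
    """
    p = len(key)
    if not 1 <= max_size <= p:
        raise ValueError(f"max_size must be in 1..{p}")
    total = sum(comb(p, s) for s in range(1, max_size + 1))
    if total > budget:
        raise ValueError(
            f"{total} combinations exceed the budget of {budget}; lower max_size or max_rank"
        )
    y = np.asarray(labels).astype(int)
    mz = key.feature_mz

    best = None  # (cv auc, -size)
    best_feats = None
    best_singleton = -np.inf
    search_log = {}
    for size in range(1, max_size + 1):
        count = 0
        for idx in combinations(range(p), size):
            feats = tuple(sorted(float(mz[j]) for j in idx))
            auc = _score_subset(matrix, y, feats, cv, n_repeats)
            if size == 1:
                best_singleton = max(best_singleton, auc)
            if best is None or auc > best[0] + 1e-15 or (
                abs(auc - best[0]) <= 1e-15 and (size < -best[1] or (size == -best[1] and feats < best_feats))
            ):
                best = (auc, -size)
                best_feats = feats
            count += 1
        search_log[size] = count

    panel_model = _fit_subset(matrix, y, best_feats, cv)
    disc = evaluate_roc(panel_model, matrix.subset_features(best_feats), y)
    val = None
    if validation_matrix is not None:
        val = evaluate_roc(
            panel_model, validation_matrix.subset_features(best_feats),
            np.asarray(validation_labels).astype(int), threshold=disc.threshold,
        )
    return PanelResult(
        features=np.asarray(best_feats),
        discovery_auc=disc,
        validation_auc=val,
        search_log=search_log,
        model=panel_model,
        search_score=float(best[0]),
        best_singleton_auc=float(best_singleton),
    )


def evaluate_panel_external(panel: PanelResult, external_matrix: FingerprintMatrix,
                            external_labels) -> RocResult:
    """Apply the frozen panel model (scaler + coefficients) to an external cohort."""
    for m in panel.features:
        if not np.any(np.isclose(external_matrix.feature_mz, m, rtol=0, atol=1e-6)):
            raise ValueError(f"external feature axis is missing panel feature m/z {m:.4f}")
    sub = external_matrix.subset_features(panel.features)
    y = np.asarray(external_labels).astype(int)
    return evaluate_roc(panel.model, sub, y, threshold=panel.discovery_auc.threshold)
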