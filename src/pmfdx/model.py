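"""Regularized logistic-regression diagnosis with ROC evaluation.

Workflow: stratified 70/30 split of the cohort into discovery and validation,
cross-validated grid search over L1/L2 penalty strength on the discovery
rows only (feature z-scoring is refit inside every fold), final refit on all
discovery rows, and rank-based AUC with a DeLong confidence interval and a
Youden-J operating point.  The validation cohort reuses the discovery
threshold and never touches the scaler, the tuning, or feature selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .fingerprint import FingerprintMatrix

__all__ = [
    "SplitSpec",
    "HyperGrid",
    "FittedModel",
    "RocResult",
    "stratified_split",
    "tune_and_fit",
    "evaluate_roc",
    "rank_auc",
    "delong_variance",
]


@dataclass(frozen=True)
class SplitSpec:
    discovery_frac: float = 0.7
    stratify_on: str = "mmd_grade"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.discovery_frac < 1:
            raise ValueError("discovery_frac must be in (0, 1)")


@dataclass(frozen=True)
class HyperGrid:
    """Penalty / strength grid for cross-validated tuning.

    ``strength_grid`` holds regularization strengths lambda (sklearn C = 1/lambda);
    the default spans six orders of magnitude in 13 log-spaced steps.
    """

    penalties: tuple = ("l1", "l2")
    strength_grid: tuple = tuple(np.logspace(-3, 3, 13))
    n_folds: int = 5
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if not self.penalties or not self.strength_grid:
            raise ValueError("penalties and strength_grid must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(s <= 0 for s in self.strength_grid):
            raise ValueError("strengths must be positive")

    @property
    def candidates(self) -> list:
        return [(p, float(s)) for p in self.penalties for s in self.strength_grid]


def stratified_split(metadata: pd.DataFrame, spec: SplitSpec):
    """Split sample ids into (discovery, validation), stratified and seeded.

    Within each stratum ``round(frac * n)`` samples go to discovery, so every
    stratum's split is within one sample of the exact proportion.
    """
    if spec.stratify_on not in metadata.columns:
        raise ValueError(f"stratification column {spec.stratify_on!r} not in metadata")
    rng = np.random.default_rng(spec.seed)
    discovery, validation = [], []
    for _, grp in metadata.groupby(spec.stratify_on, sort=True):
        ids = grp["sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"stratum of size {len(ids)} cannot be split")
        n_disc = int(round(spec.discovery_frac * len(ids)))
        n_disc = min(max(n_disc, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        chosen = set(perm[:n_disc].tolist())
        discovery.extend(ids[i] for i in range(len(ids)) if i in chosen)
        validation.extend(ids[i] for i in range(len(ids)) if i not in chosen)
    order = {sid: i for i, sid in enumerate(metadata["sample_id"])}
    discovery.sort(key=order.__getitem__)
    validation.sort(key=order.__getitem__)
    return discovery, validation


@dataclass
class FittedModel:
    """Regularized LR state: coefficients on z-scored features plus the scaler."""

    feature_mz: np.ndarray
    coefficients: np.ndarray
    intercept: float
    penalty: str
    strength: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    cv_auc: float = float("nan")

    def predict_scores(self, matrix) -> np.ndarray:
        """Probability of the positive class for each row."""
        x = matrix.values if isinstance(matrix, FingerprintMatrix) else np.asarray(matrix, dtype=float)
        z = (x - self.scaler_mean) / self.scaler_sd
        return expit(z @ self.coefficients + self.intercept)

    def to_json(self, path=None) -> str:
        payload = {
            "penalty": self.penalty,
            "strength": self.strength,
            "intercept": float(self.intercept),
            "cv_auc": None if np.isnan(self.cv_auc) else float(self.cv_auc),
            "coefficients": {f"{m:.4f}": float(c) for m, c in zip(self.feature_mz, self.coefficients)},
            "scaler_mean": {f"{m:.4f}": float(v) for m, v in zip(self.feature_mz, self.scaler_mean)},
            "scaler_sd": {f"{m:.4f}": float(v) for m, v in zip(self.feature_mz, self.scaler_sd)},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _fit_scaler(x: np.ndarray):
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _fit_lr(xz: np.ndarray, y: np.ndarray, penalty: str, strength: float):
    """Fit the regularized LR; returns (coefficients, intercept).

    The intercept is treated as unpenalized: liblinear's intercept column is
    up-weighted so its shrinkage is negligible, and in the fully sparse limit
    (every coefficient driven to zero) the intercept is set to its analytic
    maximum-likelihood value, the prevalence log-odds.
    """
    if penalty == "l1":
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / strength, solver="liblinear",
                                 intercept_scaling=1e3, max_iter=3000, tol=1e-8)
    else:
        clf = LogisticRegression(C=1.0 / strength, solver="lbfgs", max_iter=3000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(xz, y)
    coefs = clf.coef_.ravel().copy()
    intercept = float(clf.intercept_[0])
    if np.all(np.abs(coefs) < 1e-12):
        coefs[:] = 0.0
        prev = float(np.mean(y))
        prev = min(max(prev, 1e-12), 1 - 1e-12)
        intercept = float(np.log(prev / (1 - prev)))
    return coefs, intercept


def rank_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) statistic with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cross_validated_auc(x: np.ndarray, y: np.ndarray, penalty: str, strength: float,
                        n_folds: int, fold_seed: int) -> float:
    """Mean held-out AUC over stratified folds; scaler refit per fold."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    aucs = []
    for train, test in skf.split(x, y):
        mean, sd = _fit_scaler(x[train])
        coefs, intercept = _fit_lr((x[train] - mean) / sd, y[train], penalty, strength)
        scores = (x[test] - mean) / sd @ coefs + intercept
        aucs.append(rank_auc(scores, y[test]))
    return float(np.mean(aucs))


def tune_and_fit(matrix, labels, grid: HyperGrid = HyperGrid(), feature_mz=None) -> FittedModel:
    """Grid-search (penalty, strength) by mean CV AUC and refit on all rows.

    Ties favor stronger regularization, then L1 before L2.  With a single
    candidate the CV step is skipped and the model is fit directly.
    """
    if isinstance(matrix, FingerprintMatrix):
        x = matrix.values
        feature_mz = matrix.feature_mz
    else:
        x = np.asarray(matrix, dtype=float)
        if feature_mz is None:
            feature_mz = np.arange(x.shape[1], dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")

    candidates = grid.candidates
    if len(candidates) == 1:
        best_pen, best_strength = candidates[0]
        best_auc = float("nan")
    else:
        results = []
        for pen, strength in candidates:
            auc = cross_validated_auc(x, y, pen, strength, grid.n_folds, grid.fold_seed)
            results.append((auc, strength, 0 if pen == "l1" else 1, pen))
        results.sort(key=lambda r: (-r[0], -r[1], r[2]))
        best_auc, best_strength, _, best_pen = results[0]

    mean, sd = _fit_scaler(x)
    coefs, intercept = _fit_lr((x - mean) / sd, y, best_pen, best_strength)
    return FittedModel(
        feature_mz=np.asarray(feature_mz, dtype=float),
        coefficients=coefs,
        intercept=intercept,
        penalty=best_pen,
        strength=float(best_strength),
        scaler_mean=mean,
        scaler_sd=sd,
        cv_auc=best_auc,
    )


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value_vs_half: float
    sensitivity: float
    specificity: float
    threshold: float
    curve_points: list = field(default_factory=list)  # (FPR, TPR)

    def to_json(self, path=None) -> str:
        payload = {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value_vs_half": self.p_value_vs_half,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "threshold": self.threshold,
            "curve_points": [[float(a), float(b)] for a, b in self.curve_points],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimate (structural components)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # placement values via midranks
    all_ranks = rankdata(scores)
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[y == 1] - pos_ranks) / n          # P(neg < pos) per positive
    v01 = 1.0 - (all_ranks[y == 0] - neg_ranks) / m    # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def _roc_curve(scores: np.ndarray, y: np.ndarray):
    """(FPR, TPR) at every distinct threshold, predicting positive at score >= t."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    sens, spec = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        pts.append((fp / n_neg, tp / n_pos))
        sens.append(tp / n_pos)
        spec.append(1 - fp / n_neg)
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts, thresholds, np.asarray(sens), np.asarray(spec)


def evaluate_roc(scores_or_model, matrix_or_labels, labels=None, *, threshold=None,
                 n_boot: int = 0, seed: int = 0) -> RocResult:
    """ROC evaluation: rank AUC, DeLong 95% CI and p-value vs 0.5, Youden point.

    Call either as ``evaluate_roc(model, matrix, labels)`` or directly as
    ``evaluate_roc(scores, labels)``.  If ``threshold`` is given it is reused
    (validation-cohort convention); otherwise the threshold maximizing
    Youden's J (ties: higher sensitivity) is chosen on this data.  With
    ``n_boot > 0`` the CI is additionally computed by bootstrap (percentile);
    useful for single-feature panels where DeLong can degenerate.
    """
    if isinstance(scores_or_model, FittedModel):
        scores = scores_or_model.predict_scores(matrix_or_labels)
        y = np.asarray(labels).astype(int)
    else:
        scores = np.asarray(scores_or_model, dtype=float)
        y = np.asarray(matrix_or_labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")

    auc = rank_auc(scores, y)
    var = delong_variance(scores, y)
    se = float(np.sqrt(max(var, 0.0)))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        boots = []
        for _ in range(n_boot):
            bp = rng.choice(idx_pos, idx_pos.size, replace=True)
            bn = rng.choice(idx_neg, idx_neg.size, replace=True)
            bidx = np.concatenate([bp, bn])
            boots.append(rank_auc(scores[bidx], y[bidx]))
        ci_low, ci_high = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    else:
        ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
        ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    if se > 0:
        p = float(2 * norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else float(np.finfo(float).tiny)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))

    pts, thresholds, sens, spec = _roc_curve(scores, y)
    if threshold is None:
        j = sens + spec - 1.0
        best = max(range(thresholds.size), key=lambda i: (j[i], sens[i]))
        threshold = float(thresholds[best])
        sensitivity, specificity = float(sens[best]), float(spec[best])
    else:
        pred = scores >= threshold
        sensitivity = float(np.sum(pred & (y == 1)) / y.sum())
        specificity = float(np.sum(~pred & (y == 0)) / (y.size - y.sum()))
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high, p_value_vs_half=p,
        sensitivity=sensitivity, specificity=specificity,
        threshold=float(threshold), curve_points=pts,
    )
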