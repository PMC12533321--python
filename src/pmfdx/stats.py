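"""Univariate statistics: Welch tests, Kendall correlations, BH-FDR and
pilot power curves.

The power analysis follows the standard pilot-study recipe for omics panels:
estimate per-feature standardized effects (Cohen's d) from a small pilot,
approximate the per-test significance threshold that Benjamini-Hochberg
control at the chosen FDR would grant, and predict two-sample t-test power
at that threshold over a grid of per-group sample sizes via the noncentral
t distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fingerprint import FingerprintMatrix

__all__ = [
    "welch_t_two_tailed",
    "kendall_tau",
    "bh_adjust",
    "cohens_d",
    "two_sample_t_power",
    "pilot_power_curve",
    "kendall_network",
    "PowerCurve",
    "CorrelationNetwork",
]


def welch_t_two_tailed(x, y):
    """Welch two-sample t (Satterthwaite df), two-tailed p.

    Zero variance in both groups: p = 1 when the means are equal (by
    convention), else the statistic is +/-inf with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def kendall_tau(x, y):
    """Kendall tau-b with tie correction.

    p by exact enumeration for n <= 8 tie-free inputs, else by the normal
    approximation.  A constant input leaves tau undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "exact" if (x.size <= 8 and not ties) else "asymptotic"
    res = sps.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags at level q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled-SD denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else float(np.inf) * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / pooled)


def two_sample_t_power(d: float, n_per_group: int, alpha: float) -> float:
    """Two-sided two-sample t-test power from the noncentral t distribution.

    Falls back to the normal approximation where scipy's noncentral-t
    evaluation loses accuracy (large noncentrality); there the power is
    indistinguishable from 1 anyway.
    """
    df = 2 * n_per_group - 2
    if df < 1:
        return float("nan")
    nc = abs(d) * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    with np.errstate(all="ignore"):
        power = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    if not np.isfinite(power):
        power = float(sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc))
    return min(max(power, 0.0), 1.0)


@dataclass
class PowerCurve:
    n_grid: list
    predicted_power: list
    fdr_level: float | None
    per_test_alpha: float
    pilot_effect_sizes: dict    # feature_mz -> Cohen's d
    top_k: int

    def to_json(self, path=None) -> str:
        payload = {
            "n_grid": [int(n) for n in self.n_grid],
            "predicted_power": [float(p) for p in self.predicted_power],
            "fdr_level": self.fdr_level,
            "per_test_alpha": self.per_test_alpha,
            "top_k": self.top_k,
            "pilot_effect_sizes": {f"{m:.4f}": float(d) for m, d in self.pilot_effect_sizes.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def pilot_power_curve(pilot: FingerprintMatrix, labels, n_grid,
                      fdr: float | None = 0.15, top_k: int = 25,
                      alpha: float = 0.05) -> PowerCurve:
    """Predicted power versus per-group sample size from pilot fingerprints.

    Per-feature Cohen's d and Welch p-values are computed from the pilot.
    With ``fdr`` set, the per-test threshold is the BH-granted level
    ``fdr * r / m`` where r is the number of BH rejections of the pilot
    p-values at that FDR (floor r = 1, the least favorable non-empty
    rejection set); with ``fdr=None`` the plain ``alpha`` is used.  Predicted
    power at each n is the mean noncentral-t power of the ``top_k`` features
    by |d|.
    """
    y = np.asarray(labels).astype(int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("pilot needs at least 2 samples per class")
    ds, ps = [], []
    for j in range(pilot.n_features):
        col = pilot.values[:, j]
        ds.append(cohens_d(col[y == 1], col[y == 0]))
        ps.append(welch_t_two_tailed(col[y == 1], col[y == 0])[1])
    ds = np.asarray(ds)
    ps = np.asarray(ps)

    if fdr is None:
        per_test_alpha = float(alpha)
    else:
        _, reject = bh_adjust(ps, q=fdr)
        r = max(int(reject.sum()), 1)
        per_test_alpha = float(fdr * r / ps.size)

    finite = np.isfinite(ds)
    order = np.argsort(-np.abs(np.where(finite, ds, -np.inf)), kind="stable")
    k = min(top_k, int(finite.sum())) or 1
    top = order[:k]
    power = [float(np.mean([two_sample_t_power(ds[j], int(n), per_test_alpha) for j in top]))
             for n in n_grid]
    effects = {float(pilot.feature_mz[j]): float(ds[j]) for j in top}
    return PowerCurve(
        n_grid=list(n_grid), predicted_power=power, fdr_level=fdr,
        per_test_alpha=per_test_alpha, pilot_effect_sizes=effects, top_k=k,
    )


@dataclass
class CorrelationNetwork:
    pairs: list                 # (mz_a, mz_b, tau, p)
    alpha: float

    @property
    def significant(self) -> list:
        return [p for p in self.pairs if np.isfinite(p[3]) and p[3] < self.alpha]

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "pairs": [
                {"a": f"{a:.4f}", "b": f"{b:.4f}",
                 "tau": None if not np.isfinite(t) else float(t),
                 "p": None if not np.isfinite(p) else float(p)}
                for a, b, t, p in self.pairs
            ],
            "n_significant": len(self.significant),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def kendall_network(matrix: FingerprintMatrix, feature_mz=None, alpha: float = 0.1) -> CorrelationNetwork:
    """All-pairs Kendall tau-b among the given features (default: all)."""
    sub = matrix if feature_mz is None else matrix.subset_features(feature_mz)
    pairs = []
    for i, j in combinations(range(sub.n_features), 2):
        tau, p = kendall_tau(sub.values[:, i], sub.values[:, j])
        pairs.append((float(sub.feature_mz[i]), float(sub.feature_mz[j]), tau, p))
    return CorrelationNetwork(pairs=pairs, alpha=alpha)
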