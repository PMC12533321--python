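"""Replicate reproducibility QC: per-feature CVs and replicate correlations."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprint import FingerprintMatrix

__all__ = ["QcReport", "feature_cvs", "qc_summary"]


@dataclass
class QcReport:
    """CV summary over a replicate fingerprint matrix.

    ``per_feature_cv`` maps feature m/z to CV (NaN where the feature mean is
    zero; such features are excluded from ``median_cv`` and ``frac_below``).
    ``pearson`` is the replicate-by-replicate correlation matrix.
    """

    per_feature_cv: pd.Series
    median_cv: float
    frac_below: dict = field(default_factory=dict)
    pearson: np.ndarray | None = None
    replicate_ids: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "median_cv": self.median_cv,
            "frac_below": {str(k): v for k, v in self.frac_below.items()},
            "per_feature_cv": {f"{m:.4f}": (None if np.isnan(v) else float(v))
                               for m, v in self.per_feature_cv.items()},
            "pearson": None if self.pearson is None else np.round(self.pearson, 12).tolist(),
            "replicate_ids": self.replicate_ids,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def feature_cvs(replicates: FingerprintMatrix) -> pd.Series:
    """Per-feature coefficient of variation across replicate rows.

    CV(f) = sd(column f, n-1 denominator) / mean(column f); features with
    zero mean are returned as NaN (undefined) so summaries can exclude them.
    """
    if replicates.n_samples < 2:
        raise ValueError("at least 2 replicate rows are required")
    values = replicates.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    # constant columns are exactly zero-variance; guard against summation error
    sd[np.ptp(values, axis=0) == 0] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, np.nan, sd / mean)
    return pd.Series(cv, index=replicates.feature_mz)


def qc_summary(replicates: FingerprintMatrix, thresholds=(0.15, 0.30)) -> QcReport:
    """Median CV, CV fraction below each threshold, and the Pearson matrix."""
    cv = feature_cvs(replicates)
    defined = cv.dropna()
    if defined.empty:
        raise ValueError("no feature has a nonzero mean; CVs are all undefined")
    frac = {float(t): float((defined < t).mean()) for t in thresholds}
    pearson = np.corrcoef(replicates.values)
    return QcReport(
        per_feature_cv=cv,
        median_cv=float(defined.median()),
        frac_below=frac,
        pearson=pearson,
        replicate_ids=list(replicates.sample_ids),
    )
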