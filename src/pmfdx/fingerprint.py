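"""Peak detection, feature alignment and fingerprint construction.

The raw input is a profile-mode LDI mass spectrum (paired m/z and intensity
arrays, ~100-1000 Da).  Peaks are detected as localized highest-intensity
points above a robust noise floor, centroided by intensity-weighted m/z,
aligned across samples into a fixed reference feature axis by single-linkage
binning, and assembled into a dense samples x features relative-intensity
matrix (the plasma metabolic fingerprint, PMF, database).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

__all__ = [
    "Spectrum",
    "PeakList",
    "FeatureAxis",
    "FingerprintMatrix",
    "detect_peaks",
    "build_feature_axis",
    "build_fingerprints",
]


@dataclass
class Spectrum:
    """One raw mass spectrum: ascending m/z (Da) with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Detected centroids for one sample: (centroid m/z, apex intensity) pairs."""

    sample_id: str
    centroid_mz: np.ndarray
    apex_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.centroid_mz = np.asarray(self.centroid_mz, dtype=float)
        self.apex_intensity = np.asarray(self.apex_intensity, dtype=float)
        if self.centroid_mz.size and np.any(np.diff(self.centroid_mz) <= 0):
            raise ValueError("centroids must be strictly increasing")
        if np.any(self.apex_intensity <= 0):
            raise ValueError("apex intensities must be positive")

    def __len__(self) -> int:
        return self.centroid_mz.size


@dataclass
class FeatureAxis:
    """Cohort-level reference m/z grid with per-feature detection frequency."""

    feature_mz: np.ndarray
    tolerance_da: float
    detection_frequency: np.ndarray

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.detection_frequency = np.asarray(self.detection_frequency, dtype=float)

    def __len__(self) -> int:
        return self.feature_mz.size


@dataclass
class FingerprintMatrix:
    """Samples x features relative-intensity table (dense; absent peak = 0)."""

    sample_ids: list
    feature_mz: np.ndarray
    values: np.ndarray
    normalization_tag: str = "none"
    flagged_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.feature_mz.size):
            raise ValueError("values shape must be (n_samples, n_features)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return self.feature_mz.size

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{m:.4f}" for m in self.feature_mz]
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols)

    def subset_samples(self, sample_ids) -> "FingerprintMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FingerprintMatrix(
            sample_ids=list(sample_ids),
            feature_mz=self.feature_mz.copy(),
            values=self.values[idx],
            normalization_tag=self.normalization_tag,
            flagged_samples=[s for s in self.flagged_samples if s in set(sample_ids)],
        )

    def subset_features(self, feature_mz) -> "FingerprintMatrix":
        want = np.asarray(feature_mz, dtype=float)
        idx = []
        for m in want:
            j = int(np.argmin(np.abs(self.feature_mz - m)))
            if not np.isclose(self.feature_mz[j], m, rtol=0, atol=1e-6):
                raise KeyError(f"feature m/z {m:.4f} not on this axis")
            idx.append(j)
        return FingerprintMatrix(
            sample_ids=list(self.sample_ids),
            feature_mz=self.feature_mz[idx],
            values=self.values[:, idx],
            normalization_tag=self.normalization_tag,
            flagged_samples=list(self.flagged_samples),
        )


def mad_noise_level(intensity: np.ndarray) -> float:
    """Robust noise estimate: scaled median absolute deviation of the whole trace."""
    x = np.asarray(intensity, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def detect_peaks(spectrum: Spectrum, half_window_points: int = 10, snr_min: float = 3.0) -> PeakList:
    """Detect peaks by localized highest intensity above an SNR floor.

    A point ``i`` is a peak iff its intensity is the maximum over the closed
    index window ``i +/- half_window_points``, no tied maximum occurs at a
    lower index inside the window, and the intensity reaches
    ``snr_min * noise`` where ``noise = MAD(intensity)/0.6745`` over the whole
    spectrum.  The reported centroid is the intensity-weighted mean m/z over
    the window; the apex intensity is the raw intensity at the peak point.
    """
    if half_window_points < 1:
        raise ValueError("half_window_points must be >= 1")
    if snr_min <= 0:
        raise ValueError("snr_min must be > 0")
    n = len(spectrum)
    w = int(half_window_points)
    if 2 * w + 1 > n:
        raise ValueError(f"window of {2 * w + 1} points exceeds spectrum length {n}")

    intensity = spectrum.intensity
    noise = mad_noise_level(intensity)
    threshold = snr_min * noise

    local_max = maximum_filter1d(intensity, size=2 * w + 1, mode="constant", cval=-np.inf)
    candidates = np.flatnonzero((intensity == local_max) & (intensity >= threshold) & (intensity > 0))

    centroids, apexes = [], []
    for i in candidates:
        lo = max(0, i - w)
        # a tied maximum earlier in the window claims the peak
        if np.any(intensity[lo:i] == intensity[i]):
            continue
        hi = min(n, i + w + 1)
        weights = intensity[lo:hi]
        centroids.append(float(np.dot(spectrum.mz[lo:hi], weights) / weights.sum()))
        apexes.append(float(intensity[i]))

    centroids = np.asarray(centroids)
    apexes = np.asarray(apexes)
    order = np.argsort(centroids, kind="stable")
    centroids, apexes = centroids[order], apexes[order]
    # guard against windows whose weighted centroids collide: keep the stronger
    if centroids.size > 1:
        keep = np.ones(centroids.size, dtype=bool)
        for j in range(1, centroids.size):
            if centroids[j] <= centroids[j - 1]:
                keep[j if apexes[j] < apexes[j - 1] else j - 1] = False
        centroids, apexes = centroids[keep], apexes[keep]
    return PeakList(sample_id=spectrum.sample_id, centroid_mz=centroids, apex_intensity=apexes)


def build_feature_axis(
    peaklists: list,
    tolerance_da: float = 0.1,
    min_detection_frac: float = 0.5,
    max_features: int = 200,
) -> FeatureAxis:
    """Align pooled centroids into a reference feature axis.

    Single-linkage binning: pooled centroids are sorted and split wherever
    consecutive centroids differ by more than ``tolerance_da``; each bin is
    represented by its median centroid.  Bins detected in fewer than
    ``min_detection_frac`` of samples are dropped, then the ``max_features``
    most frequently detected bins are kept (ties: higher mean apex intensity,
    then lower m/z).  The result is order-independent in the input peaklists.
    """
    if not peaklists:
        raise ValueError("at least one peaklist is required")
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be > 0")

    n_samples = len(peaklists)
    mz = np.concatenate([p.centroid_mz for p in peaklists]) if peaklists else np.array([])
    apex = np.concatenate([p.apex_intensity for p in peaklists])
    sample_idx = np.concatenate([np.full(len(p), k) for k, p in enumerate(peaklists)])
    if mz.size == 0:
        return FeatureAxis(np.array([]), tolerance_da, np.array([]))

    order = np.argsort(mz, kind="stable")
    mz, apex, sample_idx = mz[order], apex[order], sample_idx[order]
    breaks = np.flatnonzero(np.diff(mz) > tolerance_da) + 1
    bins = np.split(np.arange(mz.size), breaks)
    if len(bins) == 1 and mz.size > 1:
        warnings.warn("tolerance merged all pooled centroids into a single feature bin", stacklevel=2)

    reps, freqs, mean_apex = [], [], []
    for b in bins:
        reps.append(float(np.median(mz[b])))
        freqs.append(len(set(sample_idx[b].tolist())) / n_samples)
        mean_apex.append(float(apex[b].mean()))
    reps = np.asarray(reps)
    freqs = np.asarray(freqs)
    mean_apex = np.asarray(mean_apex)

    keep = freqs >= min_detection_frac
    reps, freqs, mean_apex = reps[keep], freqs[keep], mean_apex[keep]
    if reps.size > max_features:
        rank = sorted(range(reps.size), key=lambda i: (-freqs[i], -mean_apex[i], reps[i]))
        sel = np.sort(np.asarray(rank[:max_features]))
        reps, freqs = reps[sel], freqs[sel]
    order = np.argsort(reps)
    return FeatureAxis(feature_mz=reps[order], tolerance_da=tolerance_da, detection_frequency=freqs[order])


def build_fingerprints(peaklists: list, axis: FeatureAxis, normalization: str = "tic") -> FingerprintMatrix:
    """Map peaklists onto the feature axis and assemble the fingerprint matrix.

    Cell (s, f) holds the maximum apex intensity of sample s's peaks within
    ``feature_mz[f] +/- tolerance_da`` (closed interval), else 0.  With
    ``normalization="tic"`` each row is divided by its sum; all-zero rows are
    left as zeros and flagged.
    """
    if len(axis) == 0:
        raise ValueError("feature axis is empty")
    if normalization not in ("tic", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")

    tol = axis.tolerance_da
    values = np.zeros((len(peaklists), len(axis)))
    for s, pl in enumerate(peaklists):
        if len(pl) == 0:
            continue
        lo = np.searchsorted(pl.centroid_mz, axis.feature_mz - tol, side="left")
        hi = np.searchsorted(pl.centroid_mz, axis.feature_mz + tol, side="right")
        for f in range(len(axis)):
            if hi[f] > lo[f]:
                values[s, f] = pl.apex_intensity[lo[f]:hi[f]].max()

    flagged = []
    if normalization == "tic":
        sums = values.sum(axis=1)
        zero = sums == 0
        flagged = [peaklists[i].sample_id for i in np.flatnonzero(zero)]
        sums[zero] = 1.0
        values = values / sums[:, None]

    return FingerprintMatrix(
        sample_ids=[p.sample_id for p in peaklists],
        feature_mz=axis.feature_mz.copy(),
        values=values,
        normalization_tag=normalization,
        flagged_samples=flagged,
    )
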