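import numpy as np
import pytest

from pmfdx.fingerprint import build_feature_axis, build_fingerprints, detect_peaks
from pmfdx.pipeline import RunConfig, run_pipeline
from pmfdx.synthetic import CohortSpec, generate_cohort


def small_config(out_dir, seed=5):
    """Full study structure (125 samples, 200 features) at reduced raw size."""
    return RunConfig(
        output_dir=str(out_dir), seed=seed,
        n_points=8_000, half_window_points=2, snr_min=6.0,
        penalties=("l2",), strength_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
        max_rank=10, max_size=4,
        n_replicates=10, trend_restarts=20,
        external_n_per_grade={1: 20, 2: 14, 3: 10, 4: 8},
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The same small config executed twice with one seed (for determinism checks)."""
    base = tmp_path_factory.mktemp("runs")
    reports = [run_pipeline(small_config(base / name)) for name in ("a", "b")]
    return base, reports


@pytest.fixture(scope="session")
def cohort125():
    """Default-structure synthetic cohort (125 samples, grades 35/30/35/25)
    at a reduced raw-point count, with detected peaklists and the TIC-normalized
    200-feature fingerprint matrix."""
    spec = CohortSpec(n_points=20_000, seed=11)
    spectra, metadata = generate_cohort(spec)
    peaklists = [detect_peaks(s, half_window_points=5, snr_min=6.0) for s in spectra]
    axis = build_feature_axis(peaklists, tolerance_da=0.1, min_detection_frac=0.5, max_features=200)
    fp = build_fingerprints(peaklists, axis, normalization="tic")
    raw = build_fingerprints(peaklists, axis, normalization="none")
    return dict(spec=spec, spectra=spectra, metadata=metadata, peaklists=peaklists,
                axis=axis, fp=fp, raw=raw)


def brute_force_peak_indices(intensity: np.ndarray, w: int, snr_min: float):
    """Exhaustive O(n*w) scan of the localized-highest-intensity predicate."""
    x = np.asarray(intensity, dtype=float)
    noise = np.median(np.abs(x - np.median(x))) / 0.6745
    thr = snr_min * noise
    n = x.size
    out = []
    for i in range(n):
        if x[i] <= 0 or x[i] < thr:
            continue
        lo, hi = max(0, i - w), min(n, i + w + 1)
        ok = True
        for j in range(lo, hi):
            if j == i:
                continue
            if x[j] > x[i] or (x[j] == x[i] and j < i):
                ok = False
                break
        if ok:
            out.append(i)
    return out
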