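"""Synthetic cohort generator.

Emulates a plasma-metabolite LDI-MS study of high-myopia patients graded by
myopic macular degeneration (MMD 1-4): one profile-mode spectrum per subject
over 100-1000 Da, shared background peaks concentrated at low mass, planted
biomarker peaks whose group means follow fixed trend archetypes over the
three clinical groups {simple HM, MMD 2-3, MMD 4}, plus replicate series for
reproducibility QC.  Everything is driven by a single integer seed and is
bit-reproducible.

Peak model: Gaussian shapes with FWHM = m/5000 (TOF-like resolving power);
per-peak base intensities are lognormal(0, 1), scaled to a common total ion
current per sample; per-sample variation is an independent lognormal jitter
per peak.  Group effects act multiplicatively on the planted peak's true
intensity (a shift on the log scale), expressed on the Cohen's-d scale of the
log-intensity noise so a ``standardized_effect`` of 1.0 produces an empirical
standardized mean difference near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fingerprint import Spectrum

__all__ = [
    "PlantedEffect",
    "CohortSpec",
    "ARCHETYPES",
    "generate_cohort",
    "generate_replicate_series",
    "default_effects",
    "grade_to_group3",
]

# sign pattern of group means over (simple HM, MMD 2-3, MMD 4)
ARCHETYPES = {
    "consistently-up": (0.0, 1.0, 1.0),
    "consistently-down": (0.0, -1.0, -1.0),
    "MMD4-specific-down": (0.0, 0.0, -1.0),
    "MMD23-specific-down": (0.0, -1.0, 0.0),
    "flat": (0.0, 0.0, 0.0),
}

GROUP_ORDER = ("simple HM", "MMD 2-3", "MMD 4")


def grade_to_group3(grade: int) -> str:
    return "simple HM" if grade == 1 else ("MMD 2-3" if grade in (2, 3) else "MMD 4")


@dataclass(frozen=True)
class PlantedEffect:
    """A biomarker feature with a known group-trend archetype.

    ``standardized_effect`` is the per-group shift, on the Cohen's-d scale of
    the log-intensity noise, applied with the archetype's sign pattern
    relative to the simple-HM baseline.
    """

    mz: float
    archetype: str
    standardized_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; expected one of {sorted(ARCHETYPES)}")

    @property
    def pattern(self) -> tuple:
        return ARCHETYPES[self.archetype]


def default_effects() -> list:
    """Twelve planted biomarkers, three per non-flat archetype, d = 0.8-1.0."""
    spec = [
        ("consistently-up", (147.30, 204.85, 621.40)),
        ("consistently-down", (118.75, 187.20, 350.60)),
        ("MMD4-specific-down", (161.05, 244.50, 470.15)),
        ("MMD23-specific-down", (131.90, 273.35, 528.70)),
    ]
    effects = []
    for archetype, mzs in spec:
        for d, mz in zip((1.0, 0.9, 0.8), mzs):
            effects.append(PlantedEffect(mz=mz, archetype=archetype, standardized_effect=d))
    return effects


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 125 subjects split 35/30/35/25 over
    MMD grades 1-4, ~120k raw points per spectrum at 100-1000 Da, 260
    background peaks (60% at 100-400 Da), replicate CV 12%.
    """

    n_per_grade: dict = field(default_factory=lambda: {1: 35, 2: 30, 3: 35, 4: 25})
    n_points: int = 120_000
    mass_range: tuple = (100.0, 1000.0)
    n_background_peaks: int = 260
    biomarker_effects: list = field(default_factory=default_effects)
    replicate_noise_cv: float = 0.12
    seed: int = 0
    # nuisance parameters of the generative model
    resolution: float = 5000.0          # FWHM = m / resolution
    peak_log_sigma: float = 0.25        # per-sample lognormal jitter (log-SD)
    baseline_noise_rel: float = 0.01    # baseline noise SD / mean apex intensity
    low_mass_frac: float = 0.60         # fraction of background peaks at 100-400 Da
    total_intensity: float = 1.0e6      # common per-sample TIC of true apexes
    cohort_role: str = "main"
    layout_seed: int | None = None      # peak positions/base intensities; None -> seed

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.n_per_grade.values()):
            raise ValueError("grade counts must be >= 0")
        if any(c == 0 for c in self.n_per_grade.values()):
            raise ValueError("requested grade with zero samples")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError("mass_range low must be < high")
        if self.replicate_noise_cv < 0:
            raise ValueError("replicate_noise_cv must be >= 0")
        for eff in self.biomarker_effects:
            if not (lo <= eff.mz <= hi):
                raise ValueError(f"planted m/z {eff.mz} outside mass range {self.mass_range}")


def _background_positions(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Background peak m/z, skewed to low mass, min 0.3 Da apart and clear of planted peaks."""
    lo, hi = spec.mass_range
    low_hi = min(400.0, hi)
    planted = np.array([e.mz for e in spec.biomarker_effects])
    taken = list(planted)
    out = []
    n_low = int(round(spec.low_mass_frac * spec.n_background_peaks)) if low_hi > lo else 0
    for k in range(spec.n_background_peaks):
        a, b = (lo, low_hi) if k < n_low else (low_hi, hi)
        if a >= b:
            a, b = lo, hi
        for _ in range(1000):
            m = rng.uniform(a, b)
            if not taken or np.min(np.abs(np.asarray(taken) - m)) > 0.3:
                out.append(m)
                taken.append(m)
                break
        else:  # pragma: no cover - pathological density
            raise RuntimeError("could not place background peaks 0.3 Da apart")
    return np.sort(np.asarray(out))


def _snap_to_grid(mz_grid: np.ndarray, peak_mz: np.ndarray) -> np.ndarray:
    """Peak centers snapped to the nearest sampled m/z.

    Keeps peaks narrower than the grid spacing from falling between samples;
    at the full raw-point density the shift is far below the alignment
    tolerance.
    """
    idx = np.clip(np.searchsorted(mz_grid, peak_mz), 1, mz_grid.size - 1)
    left_closer = (peak_mz - mz_grid[idx - 1]) < (mz_grid[idx] - peak_mz)
    return mz_grid[np.where(left_closer, idx - 1, idx)]


def _render_spectrum(
    mz_grid: np.ndarray,
    peak_mz: np.ndarray,
    apex: np.ndarray,
    noise_sd: float,
    resolution: float,
    rng: np.random.Generator,
    sample_id: str,
) -> Spectrum:
    intensity = np.abs(rng.normal(0.0, noise_sd, size=mz_grid.size)) if noise_sd > 0 else np.zeros(mz_grid.size)
    centers = _snap_to_grid(mz_grid, peak_mz)
    sigma = (centers / resolution) / 2.3548200450309493  # FWHM -> Gaussian sigma
    lo_idx = np.searchsorted(mz_grid, centers - 4 * sigma)
    hi_idx = np.searchsorted(mz_grid, centers + 4 * sigma) + 1
    for m, a, s, i0, i1 in zip(centers, apex, sigma, lo_idx, np.minimum(hi_idx, mz_grid.size)):
        if i1 > i0:
            x = mz_grid[i0:i1]
            intensity[i0:i1] += a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return Spectrum(mz=mz_grid, intensity=intensity, sample_id=sample_id)


def _true_layout(spec: CohortSpec, rng: np.random.Generator):
    """Shared peak positions and base intensities for a cohort or replicate series."""
    bg_mz = _background_positions(spec, rng)
    planted_mz = np.array([e.mz for e in spec.biomarker_effects])
    peak_mz = np.concatenate([bg_mz, planted_mz])
    base = rng.lognormal(0.0, 1.0, size=peak_mz.size)
    # planted biomarkers get a mid-to-high base so they are reliably detectable
    # and survive the feature-axis frequency/intensity cap
    base[bg_mz.size:] = np.exp(rng.uniform(0.5, 1.2, size=planted_mz.size))
    order = np.argsort(peak_mz)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)
    planted_cols = inverse[bg_mz.size:]  # positions of planted peaks after sorting
    return peak_mz[order], base[order], planted_cols


def generate_cohort(spec: CohortSpec):
    """Generate one spectrum per subject plus a metadata table.

    Returns ``(spectra, metadata)`` where metadata has columns
    ``sample_id, mmd_grade, pm_label, group3, cohort_role``.
    """
    layout_rng = np.random.default_rng(spec.seed if spec.layout_seed is None else spec.layout_seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lo, hi = spec.mass_range
    mz_grid = np.linspace(lo, hi, spec.n_points)
    peak_mz, base, planted_cols = _true_layout(spec, layout_rng)

    patterns = np.array([e.pattern for e in spec.biomarker_effects])
    d_effect = np.array([e.standardized_effect for e in spec.biomarker_effects])

    records = []
    grades = []
    for grade in sorted(spec.n_per_grade):
        grades.extend([grade] * spec.n_per_grade[grade])
    spectra = []
    mean_apex = spec.total_intensity / peak_mz.size
    noise_sd = spec.baseline_noise_rel * mean_apex
    for k, grade in enumerate(grades):
        sid = f"S{k + 1:03d}"
        group = grade_to_group3(grade)
        gidx = GROUP_ORDER.index(group)
        log_shift = np.zeros(peak_mz.size)
        log_shift[planted_cols] = d_effect * spec.peak_log_sigma * patterns[:, gidx]
        jitter = rng.lognormal(0.0, spec.peak_log_sigma, size=peak_mz.size)
        apex = base * jitter * np.exp(log_shift)
        apex *= spec.total_intensity / apex.sum()
        spectra.append(_render_spectrum(mz_grid, peak_mz, apex, noise_sd, spec.resolution, rng, sid))
        records.append(
            dict(sample_id=sid, mmd_grade=grade, pm_label=int(grade >= 2), group3=group,
                 cohort_role=spec.cohort_role)
        )
    return spectra, pd.DataFrame.from_records(records)


def generate_replicate_series(spec: CohortSpec, n_replicates: int):
    """Repeatedly 'measure' one pooled sample.

    All replicates share one true peak pattern and one baseline-noise
    realization; each replicate jitters every peak's intensity with
    independent multiplicative noise of coefficient of variation
    ``replicate_noise_cv`` (so a CV of 0 returns bit-identical spectra).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    layout_rng = np.random.default_rng(spec.seed if spec.layout_seed is None else spec.layout_seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    lo, hi = spec.mass_range
    mz_grid = np.linspace(lo, hi, spec.n_points)
    peak_mz, base, _ = _true_layout(spec, layout_rng)
    apex_true = base * (spec.total_intensity / base.sum())
    mean_apex = spec.total_intensity / peak_mz.size
    noise_sd = spec.baseline_noise_rel * mean_apex
    baseline = np.abs(rng.normal(0.0, noise_sd, size=mz_grid.size)) if noise_sd > 0 else np.zeros(mz_grid.size)

    sigma_log = float(np.sqrt(np.log1p(spec.replicate_noise_cv**2)))
    centers = _snap_to_grid(mz_grid, peak_mz)
    sigma = (centers / spec.resolution) / 2.3548200450309493
    lo_idx = np.searchsorted(mz_grid, centers - 4 * sigma)
    hi_idx = np.minimum(np.searchsorted(mz_grid, centers + 4 * sigma) + 1, mz_grid.size)

    spectra = []
    for r in range(n_replicates):
        jitter = rng.lognormal(0.0, sigma_log, size=peak_mz.size) if sigma_log > 0 else np.ones(peak_mz.size)
        apex = apex_true * jitter
        intensity = baseline.copy()
        for m, a, s, i0, i1 in zip(centers, apex, sigma, lo_idx, hi_idx):
            if i1 > i0:
                x = mz_grid[i0:i1]
                intensity[i0:i1] += a * np.exp(-0.5 * ((x - m) / s) ** 2)
        spectra.append(Spectrum(mz=mz_grid, intensity=intensity, sample_id=f"R{r + 1:03d}"))
    return spectra


def external_cohort_spec(spec: CohortSpec, seed_offset: int = 10_000, null: bool = False) -> CohortSpec:
    """Spec for an independent external cohort under the same generative model.

    ``null=True`` removes all planted effects (label-uninformative transfer
    control) while keeping the feature layout compatible.
    """
    effects = (
        [replace(e, standardized_effect=0.0) for e in spec.biomarker_effects]
        if null
        else list(spec.biomarker_effects)
    )
    layout = spec.seed if spec.layout_seed is None else spec.layout_seed
    return replace(
        spec,
        seed=spec.seed + seed_offset,
        layout_seed=layout,
        biomarker_effects=effects,
        cohort_role="external",
    )
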