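# Methods

## The problem and the pipeline

High myopia with myopic macular degeneration (MMD) of grade ≥ 2 defines
pathologic myopia (PM). The package implements a metabolic-fingerprint
screening workflow for this diagnosis: plasma LDI mass spectra are reduced
to a fixed vector of relative peak intensities (the plasma metabolic
fingerprint, PMF), a regularized logistic regression is trained to separate
PM from simple high myopia (and, separately, MMD 4 from MMD 2–3), and a
small biomarker panel is distilled from the full model. Because the
underlying patient spectra are not publicly deposited, the package ships a
synthetic cohort generator whose outputs have the statistical structure the
analysis assumes; all tests and the acceptance script run against it.

## Generative model of the synthetic cohort

One spectrum per subject on a uniform m/z grid over 100–1000 Da
(`n_points`, default 120 000). Peaks are Gaussian with FWHM = m/5000
(TOF-like resolving power); each peak center is snapped to the nearest grid
point so that peaks narrower than the grid spacing cannot fall between
samples (at the default density the shift is < 0.004 Da, far below the
0.1 Da alignment tolerance).

- **Background peaks** (`n_background_peaks`, default 260): positions drawn
  uniformly, 60% in 100–400 Da and 40% in 400–1000 Da, at least 0.3 Da
  apart; per-peak base intensities are lognormal(0, 1). The default count
  is chosen so the frequency-capped axis of 200 features is fully occupied.
- **Planted biomarkers** (default 12, three per non-flat archetype, at
  standardized effects 1.0/0.9/0.8): base intensities in the mid-to-high
  range (`exp U(0.5, 1.2)`) so they are reliably detected and survive the
  axis cap. Group effects act multiplicatively (a shift on the log scale)
  with the archetype's sign pattern over (simple HM, MMD 2–3, MMD 4):
  consistently-up (0,+,+), consistently-down (0,−,−), MMD4-specific-down
  (0,0,−), MMD23-specific-down (0,−,0), flat (0,0,0). The shift is
  `standardized_effect × σ_log`, so the planted Cohen's d on log intensity
  equals the nominal value; after detection and TIC normalization the
  measured linear-scale d is within roughly ±20% of nominal.
- **Per-sample variation**: independent lognormal jitter per peak
  (σ_log = 0.25); each sample's true apex vector is scaled to a common
  total ion current; additive half-normal baseline noise at 1% of the mean
  apex.
- **Replicate series** share one true pattern and one baseline realization;
  replicate-to-replicate variation is an independent multiplicative jitter
  per peak with CV = `replicate_noise_cv` (default 0.12), so a CV of zero
  reproduces bit-identical spectra and the recovered median feature CV
  lands in the 8–16% band around the nominal 12%.
- **External cohorts** reuse the peak layout (same `layout_seed`) with
  fresh subjects; a null variant zeroes all planted effects for transfer
  controls.

What the generator does **not** emulate: isotope envelopes, adducts,
matrix clusters, chemical-noise baselines, m/z calibration drift, batch
effects, or any covariate structure (age, sex). Passing tests therefore
demonstrate that the machinery recovers the structure it assumes — not that
the diagnostic performance would transfer to real plasma spectra.

## Peak detection and alignment

A point is a peak iff it is the maximum over the closed window
±`half_window_points`, no tied maximum occurs at a lower index in the
window, and it reaches `snr_min` × noise, with noise the scaled median
absolute deviation of the entire trace (robust to dense peak regions).
Centroids are intensity-weighted means over the window. The detection
window should correspond to roughly ±0.2 Da: wider windows let a strong
peak suppress a genuine neighbor (the strict-maximum predicate), narrower
ones admit flank noise; the defaults used at each raw density in the tests
and pipeline follow this rule.

Alignment is single-linkage binning of pooled sorted centroids at
`tolerance_da` (default 0.1 Da), each bin represented by its median; bins
seen in fewer than `min_detection_frac` (default 0.5) of samples are
dropped and the `max_features` (default 200) most frequently detected are
kept (ties: higher mean apex, then lower m/z). The procedure is
deterministic and order-independent. Replicate QC uses a 265-feature cap,
matching the deeper feature count a single-sample replicate study yields.
Absent peaks are encoded as exact zeros (non-detection in LDI is
informative); TIC normalization divides each row by its sum, flagging
all-zero rows instead of dividing.

## Modeling choices

- **Split**: stratified by MMD grade at 70/30 with per-stratum banker's
  rounding; on the 35/30/35/25 cohort this yields the 87/38 split with 24
  simple-HM and 63 PM discovery subjects. The severity task re-splits the
  90 PM subjects the same way (45/18 discovery).
- **Tuning**: stratified 5-fold CV over {L1, L2} × 13 log-spaced strengths
  spanning 10⁻³–10³; the scaler is refit inside every fold; selection by
  mean held-out AUC with ties broken toward stronger regularization, then
  L1. Solvers: liblinear for L1 (intercept up-weighted so its shrinkage is
  negligible), lbfgs for L2. In the fully sparse L1 limit the intercept is
  set analytically to the prevalence log-odds.
- **ROC**: rank-statistic AUC with ½-credit for ties; DeLong variance for
  the 95% CI and the p-value against 0.5 (percentile bootstrap available
  for degenerate cases); operating point by Youden's J on discovery, with
  the discovery threshold frozen for validation and external cohorts.
- **Panel search**: key features are the top `max_rank` (default 30;
  pipeline default 12 at desk scale) coefficients surviving a two-tailed
  Welch test at α = 0.05; all combinations of sizes 1..`max_size` (default
  6) are then scored by *repeated* stratified cross-validated discovery
  AUC (default 3 fold-assignments averaged), with ties broken toward fewer
  features then lexicographic m/z, under a 2×10⁶-combination budget.
  In-sample AUC would be monotone in panel size and always return the
  largest allowed combination; held-out scoring is what lets a small panel
  win, and repeating the folds shrinks partition noise below the ~0.01–0.02
  AUC margins that separate neighboring combinations. The reported panel
  ROC (with CI and operating point) is the in-sample refit, as a panel ROC
  figure would show; the search criterion is stored separately
  (`search_score`).
- **Trend clustering**: per-feature group means in the fixed order
  (simple HM, MMD 2–3, MMD 4), z-scored within the feature (population SD)
  so that only the shape matters; k-means (k = 5, 50 seeded k-means++
  restarts, lowest within-cluster sum of squares kept) on the non-flat
  profiles; flat profiles (SD < 10⁻¹²) are attached to the centroid nearest
  the origin afterwards. Cluster ids are relabeled by descending first-group
  centroid value so runs are comparable.
- **Power analysis**: per-feature Cohen's d and Welch p-values from the
  pilot (5 + 5 subjects in the pipeline); with an FDR level f, the per-test
  threshold is the BH-granted level `f·r/m` (r = BH rejections of the pilot
  p-values at f, floored at 1); predicted power at each per-group n is the
  mean noncentral-t power of the top `top_k` features by |d|. Where scipy's
  noncentral-t loses accuracy (large noncentrality) the normal
  approximation is substituted; power is clamped to [0, 1].
- **Kendall network**: tau-b with tie correction over all panel-feature
  pairs; exact p for n ≤ 8 without ties, normal approximation otherwise;
  significance reported at α = 0.1.
- **BH adjustment** delegates to statsmodels' step-up implementation.

## Determinism and numerics

Every random choice flows from explicit integer seeds (cohort seed, split
seed, fold seed, k-means seed); the pipeline manifest records a SHA-256 per
artifact and is byte-identical across reruns with the same config and seed.
Degenerate inputs have defined behavior: zero-variance features are left
unscaled (z = 0), zero-mean features have undefined CV and are excluded
from summaries, constant replicate columns report exactly zero CV, Welch
tests on two zero-variance equal-mean samples return p = 1, and constant
vectors leave Kendall's tau undefined (flagged).

## Problem sizes

Tests and the acceptance script keep the full cohort structure (125
subjects, grade counts 35/30/35/25, 260 background peaks, 200-feature
axis, 20 replicates, 123-subject external cohort) but run spectra at
8 000–30 000 raw points instead of 120 000 and use a 12-feature key set for
the panel search; the detection window is scaled to the same ±0.2 Da at
each density. These are the package's own desk-scale defaults; all
structural results (feature counts, CV calibration, archetype recovery,
AUC behavior) are unchanged by the density.

## Known limitations

- Best-subset panel membership is an intrinsically unstable target at
  ~85 discovery samples: the coefficient screen admits features whose
  chance association with the label is real *within* the discovery sample,
  and combinations containing them can genuinely out-score the true-effect
  subset under any discovery-only criterion. Panel AUCs transfer to
  validation and external cohorts regardless; the identity of the 5th/6th
  panel member does not. Interpret panel membership lists accordingly.
- The exhaustive search is exponential in the key-set size; the budget and
  `max_size` cap make the cost explicit rather than solving it.
- In-sample discovery ROC of the full 200-feature model is near-perfect at
  these sample sizes and is reported only for completeness; cross-validated
  and validation AUCs are the meaningful numbers.
- PCA/PLS-DA component counts and scaling, the alignment method, the CV
  protocol, the CI method, and the power-analysis recipe are all standard
  choices where the emulated workflow leaves them open; each is
  configurable at the module surface.
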