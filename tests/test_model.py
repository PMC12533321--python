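"""Stratified splitting, tuned logistic regression, ROC/DeLong inference."""

import numpy as np
import pandas as pd
import pytest

from pmfdx.fingerprint import FingerprintMatrix
from pmfdx.model import (
    HyperGrid,
    SplitSpec,
    delong_variance,
    evaluate_roc,
    rank_auc,
    stratified_split,
    tune_and_fit,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def fpmat(values):
    values = np.asarray(values, dtype=float)
    return FingerprintMatrix([f"s{i}" for i in range(values.shape[0])],
                             100.0 + np.arange(values.shape[1]), values, "none")


@pytest.fixture
def metadata125():
    grades = np.repeat([1, 2, 3, 4], [35, 30, 35, 25])
    return pd.DataFrame({"sample_id": [f"S{i:03d}" for i in range(125)], "mmd_grade": grades})


class TestStratifiedSplit:
    def test_cohort_split_sizes_match_study(self, metadata125):
        disc, val = stratified_split(metadata125, SplitSpec(0.7, "mmd_grade", 0))
        assert len(disc) == 87 and len(val) == 38
        assert not set(disc) & set(val)
        # grade-1 (simple HM) discovery count: 24, PM discovery count: 63
        g = metadata125.set_index("sample_id")["mmd_grade"]
        assert sum(g[s] == 1 for s in disc) == 24
        assert sum(g[s] >= 2 for s in disc) == 63

    def test_same_seed_same_partition(self, metadata125):
        a = stratified_split(metadata125, SplitSpec(0.7, "mmd_grade", 42))
        b = stratified_split(metadata125, SplitSpec(0.7, "mmd_grade", 42))
        assert a == b

    def test_exact_proportion_when_divisible(self):
        md = pd.DataFrame({"sample_id": [f"x{i}" for i in range(10)], "grp": [0] * 10})
        disc, val = stratified_split(md, SplitSpec(0.5, "grp", 1))
        assert len(disc) == 5 and len(val) == 5

    def test_per_stratum_proportion_within_one(self, metadata125):
        disc, _ = stratified_split(metadata125, SplitSpec(0.7, "mmd_grade", 3))
        g = metadata125.set_index("sample_id")["mmd_grade"]
        for grade, n in [(1, 35), (2, 30), (3, 35), (4, 25)]:
            got = sum(g[s] == grade for s in disc)
            assert abs(got - 0.7 * n) <= 1.0

    def test_tiny_stratum_rejected(self):
        md = pd.DataFrame({"sample_id": ["a", "b", "c"], "grp": [0, 0, 1]})
        with pytest.raises(ValueError, match="size 1"):
            stratified_split(md, SplitSpec(0.7, "grp", 0))


class TestTuneAndFit:
    def test_perfect_separation_gives_auc_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 4)) * 0.1
        x[:, 1] = y * 10 + rng.normal(size=60) * 0.1
        model = tune_and_fit(fpmat(x), y, HyperGrid(penalties=("l2",), strength_grid=(0.01, 1.0)))
        # held-out synthetic data from the same rule
        xv = rng.normal(size=(40, 4)) * 0.1
        yv = np.repeat([0, 1], 20)
        xv[:, 1] = yv * 10 + rng.normal(size=40) * 0.1
        assert rank_auc(model.predict_scores(xv * 1.0), yv) == 1.0

    def test_infinite_l1_strength_collapses_to_prevalence(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], [30, 10])  # prevalence 0.25
        x = rng.normal(size=(40, 5))
        model = tune_and_fit(fpmat(x), y, HyperGrid(penalties=("l1",), strength_grid=(1e9,)))
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-8)
        np.testing.assert_allclose(model.predict_scores(x), 0.25, atol=0.01)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tune_and_fit(fpmat(np.zeros((10, 2))), np.zeros(10), HyperGrid())

    def test_scaler_fits_training_rows_only(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 6))
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        model = tune_and_fit(fpmat(x), y, HyperGrid(penalties=("l2",), strength_grid=(1.0,)))
        np.testing.assert_allclose(model.scaler_mean, x.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(model.scaler_sd, x.std(axis=0), atol=1e-12)

    def test_validation_rows_cannot_leak(self):
        # the fit is a function of the discovery rows only
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 5))
        y = np.tile([0, 1], 20)
        grid = HyperGrid(penalties=("l2",), strength_grid=(0.1, 1.0), fold_seed=7)
        m1 = tune_and_fit(fpmat(x), y, grid)
        _ = rng.normal(size=(40, 5))  # "validation" data, never passed in
        m2 = tune_and_fit(fpmat(x), y, grid)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.strength == m2.strength and m1.penalty == m2.penalty


class TestRocEvaluation:
    def test_perfect_ranking(self):
        r = evaluate_roc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_three_of_four_concordant_pairs(self):
        r = evaluate_roc(np.array([0.9, 0.4, 0.8, 0.1]), np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(0.75)

    def test_all_tied_scores_auc_half(self):
        r = evaluate_roc(np.ones(10), np.tile([0, 1], 5))
        assert r.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(40))
    def test_rank_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid to force ties
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        assert rank_auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(5)
        r = evaluate_roc(rng.normal(size=60), rng.permutation(np.repeat([0, 1], 30)))
        pts = np.asarray(r.curve_points)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_ci_brackets_auc_and_null_p_large(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=200)
        y = rng.permutation(np.repeat([0, 1], 100))
        r = evaluate_roc(scores, y)
        assert r.ci_low <= r.auc <= r.ci_high
        assert r.p_value_vs_half > 0.001  # null data: no significance

    def test_delong_variance_positive_and_reasonable(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 50)
        scores = y + rng.normal(size=100)
        var = delong_variance(scores, y)
        assert 0 < var < 0.01

    def test_threshold_reuse_on_validation(self):
        y = np.array([0, 0, 1, 1])
        r = evaluate_roc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        r2 = evaluate_roc(np.array([0.1, 0.9, 0.2, 0.8]), y, threshold=r.threshold)
        assert r2.threshold == r.threshold
        assert r2.sensitivity == pytest.approx(0.5) and r2.specificity == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_roc(np.arange(4.0), np.ones(4))
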