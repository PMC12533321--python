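"""Welch tests, Kendall tau-b, BH-FDR, and pilot power curves."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmfdx.fingerprint import FingerprintMatrix
from pmfdx.stats import (
    bh_adjust,
    cohens_d,
    kendall_tau,
    pilot_power_curve,
    two_sample_t_power,
    welch_t_two_tailed,
)


def tau_b_enumeration(x, y):
    """Direct tau-b from concordant/discordant/tied pair counts."""
    c = d = tx = ty = 0
    for i, j in combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            c += 1
        else:
            d += 1
    n0 = len(x) * (len(x) - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


def bh_stepup_oracle(p):
    """Literal step-up definition: adjusted_i = min_{j>=rank(i)} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestWelch:
    def test_identical_samples_null(self):
        t, p = welch_t_two_tailed([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_direct_formula_equal_variances(self):
        t, _ = welch_t_two_tailed([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=11)
        t1, p1 = welch_t_two_tailed(x, y)
        t2, p2 = welch_t_two_tailed(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_equal_means_p_one(self):
        t, p = welch_t_two_tailed([2, 2, 2], [2, 2])
        assert t == 0.0 and p == 1.0

    def test_null_p_values_uniform(self):
        # KS uniformity over vectorized null simulations
        from scipy import stats as sps
        rng = np.random.default_rng(42)
        a = rng.normal(size=(2000, 10))
        b = rng.normal(size=(2000, 12))
        ps = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestKendall:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_counted_example(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_constant_input_flagged(self):
        tau, p = kendall_tau([1, 1, 1], [1, 2, 3])
        assert np.isnan(tau) and np.isnan(p)

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=3, max_size=8),
           st.lists(st.integers(0, 5), min_size=8, max_size=8))
    def test_matches_pair_enumeration(self, xs, ys):
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys[: len(xs)], dtype=float)
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            return
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(tau_b_enumeration(x, y), abs=1e-12)


class TestBhAdjust:
    def test_stepup_recursion_by_hand(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        np.testing.assert_allclose(adj, 0.05)
        assert rej.all()

    def test_single_p_identity(self):
        adj, _ = bh_adjust([0.2], q=0.05)
        assert adj[0] == pytest.approx(0.2)

    def test_all_ones_no_rejections(self):
        _, rej = bh_adjust([1.0, 1.0, 1.0], q=0.05)
        assert not rej.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_stepup_definition_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 60)))
        adj, rej = bh_adjust(p, q=0.1)
        oracle = bh_stepup_oracle(p)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        np.testing.assert_array_equal(rej, adj <= 0.1)


def pilot_matrix(rng, n_per_class=5, n_features=30, d=0.0):
    y = np.repeat([0, 1], n_per_class)
    x = rng.normal(size=(2 * n_per_class, n_features))
    x[:, 0] += d * y
    fp = FingerprintMatrix([f"s{i}" for i in range(2 * n_per_class)],
                           100.0 + np.arange(n_features), x - x.min() + 1.0, "none")
    return fp, y


class TestPower:
    def test_classical_two_sample_result(self):
        # d = 1.0, alpha 0.05 two-sided, n = 17/group -> power 0.80
        assert two_sample_t_power(1.0, 17, 0.05) == pytest.approx(0.80, abs=0.01)

    def test_single_feature_curve_matches_noncentral_t(self):
        rng = np.random.default_rng(0)
        fp, y = pilot_matrix(rng, n_per_class=10, n_features=1, d=1.0)
        d_hat = cohens_d(fp.values[y == 1, 0], fp.values[y == 0, 0])
        curve = pilot_power_curve(fp, y, n_grid=[17], fdr=None, top_k=1, alpha=0.05)
        assert curve.predicted_power[0] == pytest.approx(two_sample_t_power(d_hat, 17, 0.05), abs=1e-9)

    def test_null_effects_power_near_alpha(self):
        rng = np.random.default_rng(1)
        # large pilot so the per-feature d estimates shrink to ~0; averaged
        # over all features, predicted power then sits at the alpha floor
        fp, y = pilot_matrix(rng, n_per_class=500, n_features=100, d=0.0)
        curve = pilot_power_curve(fp, y, n_grid=[10, 50], fdr=None, top_k=100, alpha=0.05)
        for p in curve.predicted_power:
            assert abs(p - 0.05) < 0.05

    def test_power_non_decreasing_in_n(self):
        rng = np.random.default_rng(2)
        fp, y = pilot_matrix(rng, d=1.0)
        curve = pilot_power_curve(fp, y, n_grid=[5, 10, 20, 40], fdr=0.15, top_k=5)
        assert curve.predicted_power == sorted(curve.predicted_power)

    def test_fdr_threshold_stricter_than_alpha(self):
        rng = np.random.default_rng(3)
        fp, y = pilot_matrix(rng, d=1.5)
        curve = pilot_power_curve(fp, y, n_grid=[20], fdr=0.15, top_k=5, alpha=0.05)
        assert curve.per_test_alpha <= 0.15

    def test_calibration_against_simulated_rejection_rate(self):
        # predicted power within +/-0.03 of the empirical rejection rate
        from scipy import stats as sps
        d, n, alpha = 0.8, 20, 0.05
        rng = np.random.default_rng(4)
        a = rng.normal(d, 1, size=(1000, n))
        b = rng.normal(0, 1, size=(1000, n))
        rate = float(np.mean(sps.ttest_ind(a, b, axis=1).pvalue < alpha))
        assert abs(two_sample_t_power(d, n, alpha) - rate) < 0.03
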