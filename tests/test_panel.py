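"""Key-feature ranking and exhaustive panel combination search."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pmfdx.fingerprint import FingerprintMatrix
from pmfdx.model import FittedModel, HyperGrid
from pmfdx.panel import KeyFeatureSet, evaluate_panel_external, rank_key_features, search_panel

ONE_POINT = HyperGrid(penalties=("l2",), strength_grid=(1.0,), n_folds=2)


def fpmat(values, mz=None):
    values = np.asarray(values, dtype=float)
    mz = 100.0 + np.arange(values.shape[1]) if mz is None else np.asarray(mz, float)
    return FingerprintMatrix([f"s{i}" for i in range(values.shape[0])], mz, values, "none")


def make_model(matrix, coefficients):
    return FittedModel(
        feature_mz=matrix.feature_mz.copy(),
        coefficients=np.asarray(coefficients, dtype=float),
        intercept=0.0, penalty="l2", strength=1.0,
        scaler_mean=matrix.values.mean(axis=0),
        scaler_sd=np.where(matrix.values.std(axis=0) == 0, 1, matrix.values.std(axis=0)),
    )


def oracle_cv_auc(sub, y, n_folds=2, fold_seed=0):
    """Mean held-out AUC of an L2 LR (lambda=1), scaler refit per fold."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    aucs = []
    for tr, te in skf.split(sub, y):
        mean, sd = sub[tr].mean(0), sub[tr].std(0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=3000, tol=1e-8)
        clf.fit((sub[tr] - mean) / sd, y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function((sub[te] - mean) / sd)))
    return float(np.mean(aucs))


def oracle_best_combo(x, y, max_size, n_folds=2, fold_seed=0):
    """Independent full-enumeration loop over all subsets up to max_size,
    scored by cross-validated AUC with the search's tie-breaks (fewer
    features, then lexicographic)."""
    best = (-1.0, 0, None)
    for size in range(1, max_size + 1):
        for idx in combinations(range(x.shape[1]), size):
            auc = oracle_cv_auc(x[:, idx], y, n_folds, fold_seed)
            if auc > best[0] + 1e-15 or (
                abs(auc - best[0]) <= 1e-15 and (size < best[1] or (size == best[1] and idx < best[2]))
            ):
                best = (auc, size, idx)
    return best[0], best[2]


class TestRankKeyFeatures:
    @pytest.fixture
    def informative(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 10))
        x[:, 0] += 2.0 * y
        x[:, 3] -= 1.5 * y
        return fpmat(x), y

    def test_rank_cap_not_binding_keeps_all_significant(self, informative):
        fp, y = informative
        model = make_model(fp, np.linspace(1, 0.1, 10))
        key = rank_key_features(model, fp, y, max_rank=30, alpha=0.99)
        assert len(key) == 10

    def test_nonsignificant_top_coefficient_excluded(self, informative):
        fp, y = informative
        coefs = np.zeros(10)
        coefs[5] = 9.0  # pure-noise feature with the largest coefficient
        coefs[0] = 1.0
        key = rank_key_features(make_model(fp, coefs), fp, y, max_rank=30, alpha=0.05)
        assert 105.0 not in key.feature_mz and 100.0 in key.feature_mz

    def test_order_by_absolute_coefficient(self, informative):
        fp, y = informative
        coefs = np.zeros(10)
        coefs[[0, 3]] = [3.0, -2.0]
        key = rank_key_features(make_model(fp, coefs), fp, y, max_rank=30, alpha=0.05)
        assert list(key.feature_mz[:2]) == [100.0, 103.0]

    def test_empty_result_rejected(self):
        rng = np.random.default_rng(1)
        fp = fpmat(rng.normal(size=(40, 4)))
        y = rng.permutation(np.repeat([0, 1], 20))
        with pytest.raises(ValueError, match="no feature survived"):
            rank_key_features(make_model(fp, np.ones(4)), fp, y, max_rank=4, alpha=1e-9)


class TestSearchPanel:
    def test_single_key_feature_forced_choice(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 1)) + y[:, None]
        fp = fpmat(x)
        key = KeyFeatureSet([(100.0, 1.0, 0.01)])
        res = search_panel(key, fp, y, max_size=1, cv=ONE_POINT, n_repeats=1)
        np.testing.assert_array_equal(res.features, [100.0])

    def test_matches_independent_enumeration(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 10))
        x[:, 0] += 1.5 * y
        x[:, 4] += 1.2 * y
        x[:, 7] -= 1.4 * y
        fp = fpmat(x)
        key = KeyFeatureSet([(float(fp.feature_mz[j]), 1.0, 0.01) for j in range(10)])
        res = search_panel(key, fp, y, max_size=4, cv=ONE_POINT, n_repeats=1)
        assert res.search_log == {1: 10, 2: 45, 3: 120, 4: 210}
        best_auc, best_idx = oracle_best_combo(x, y, 4)
        np.testing.assert_array_equal(res.features, fp.feature_mz[list(best_idx)])
        assert res.search_score == pytest.approx(best_auc, abs=1e-9)
        # the panel is dominated by planted features
        assert len({100.0, 104.0, 107.0} & {float(f) for f in res.features}) >= 2

    def test_panel_beats_best_singleton(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 25)
        x = rng.normal(size=(50, 6))
        x[:, 1] += y
        x[:, 2] += y
        res = search_panel(KeyFeatureSet([(100.0 + j, 1.0, 0.01) for j in range(6)]),
                           fpmat(x), y, max_size=3, cv=ONE_POINT)
        assert res.search_score >= res.best_singleton_auc

    def test_monotone_in_max_size(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 6))
        x[:, 0] += y
        fp = fpmat(x)
        key = KeyFeatureSet([(100.0 + j, 1.0, 0.01) for j in range(6)])
        scores = [search_panel(key, fp, y, max_size=s, cv=ONE_POINT).search_score
                  for s in (1, 2, 3)]
        assert scores == sorted(scores)

    def test_combination_budget_enforced(self):
        key = KeyFeatureSet([(100.0 + j, 1.0, 0.01) for j in range(12)])
        with pytest.raises(ValueError, match="budget"):
            search_panel(key, fpmat(np.zeros((4, 12))), np.array([0, 0, 1, 1]),
                         max_size=6, cv=ONE_POINT, budget=100)


class TestExternalEvaluation:
    def test_missing_panel_feature_named_in_error(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 3)) + y[:, None] * [1.0, 0.5, 0.0]
        fp = fpmat(x)
        key = KeyFeatureSet([(float(m), 1.0, 0.01) for m in fp.feature_mz])
        res = search_panel(key, fp, y, max_size=2, cv=ONE_POINT)
        external = fpmat(rng.normal(size=(20, 2)), mz=[900.0, 901.0])
        with pytest.raises(ValueError, match=f"{res.features[0]:.4f}"):
            evaluate_panel_external(res, external, np.tile([0, 1], 10))

    def test_transfer_to_matched_external_cohort(self):
        rng = np.random.default_rng(7)

        def draw(n):
            y = np.repeat([0, 1], n // 2)
            x = rng.normal(size=(n, 5))
            x[:, 0] += 1.5 * y
            x[:, 2] += 1.5 * y
            return x, y

        x, y = draw(80)
        fp = fpmat(x)
        key = KeyFeatureSet([(float(m), 1.0, 0.01) for m in fp.feature_mz])
        res = search_panel(key, fp, y, max_size=3, cv=ONE_POINT)
        xe, ye = draw(80)
        roc = evaluate_panel_external(res, fpmat(xe), ye)
        assert abs(roc.auc - res.discovery_auc.auc) < 0.15
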