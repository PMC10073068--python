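"""PLS-DA/VIP, Lasso logistic regression, Boruta, and the tuning harness."""

import numpy as np
import pytest

import solemetab.selectors as selectors_mod
from solemetab.config import AnalysisConfig
from solemetab.selectors import (
    balanced_accuracy,
    boruta_select,
    fit_lasso_logistic,
    fit_plsda,
    lasso_lambda_max,
    standardize,
    tune_and_evaluate,
)
from solemetab.simulate import make_null_dataset


class TestBalancedAccuracy:
    def test_identities(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, np.zeros(6, dtype=int)) == 0.5
        # recalls 0.8 and 0.4 -> 0.6
        yt = np.array([0] * 5 + [1] * 5)
        yp = np.array([0, 0, 0, 0, 1, 1, 1, 0, 0, 0])
        assert balanced_accuracy(yt, yp) == pytest.approx(0.6)

    def test_label_swap_invariance(self, rng):
        yt = rng.integers(0, 2, size=40)
        yt[:2] = [0, 1]
        yp = rng.integers(0, 2, size=40)
        assert balanced_accuracy(yt, yp) == pytest.approx(balanced_accuracy(1 - yt, 1 - yp))

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.zeros(5, dtype=int), np.zeros(5, dtype=int))


class TestPLSDA:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("ncomp", [1, 3, 5])
    def test_vip_identity_sum_sq_equals_p(self, seed, ncomp):
        rng = np.random.default_rng(seed)
        n, p = 40, 12
        X = standardize(rng.normal(size=(n, p)))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        model = fit_plsda(X, y, ncomp)
        assert (model.vip**2).sum() == pytest.approx(p, abs=1e-6)

    def test_informative_variable_has_vip_above_one(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=n)])
        model = fit_plsda(standardize(X), y, 1)
        assert model.vip[0] > 1.0 > model.vip[1]
        assert model.selected_mask().tolist() == [True, False]

    def test_orthogonal_data_predicts_at_chance(self, rng):
        m, y = make_null_dataset(100, 20, seed=5)
        cfg = AnalysisConfig.reduced()
        perf, _ = tune_and_evaluate("plsda", m.values(), y, seed=1, config=cfg)
        assert perf.balanced_accuracy == pytest.approx(0.5, abs=0.12)

    def test_component_bounds_enforced(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            fit_plsda(X, y, 5)
        with pytest.raises(ValueError):
            fit_plsda(X, y, 0)


class TestLassoLogistic:
    def test_all_zero_at_and_above_lambda_max(self, rng):
        n, p = 80, 15
        X = standardize(rng.normal(size=(n, p)))
        y = np.repeat([0, 1], n // 2)
        X[:, 0] += 0.8 * (2 * y - 1)  # real signal so lambda_max is informative
        X = standardize(X)
        lam_max = lasso_lambda_max(X, y)
        for lam in (lam_max * 1.0001, lam_max * 2):
            assert (fit_lasso_logistic(X, y, lam).coef == 0).all()
        assert (fit_lasso_logistic(X, y, lam_max * 0.5).coef != 0).any()

    def test_selected_set_nonincreasing_along_path(self, rng):
        n, p = 100, 20
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:4] = [1.5, -1.0, 0.8, 0.5]
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(int)
        Xs = standardize(X)
        lam_max = lasso_lambda_max(Xs, y)
        sizes = [
            (fit_lasso_logistic(Xs, y, lam).coef != 0).sum()
            for lam in (lam_max, lam_max / 2, lam_max / 10)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_consistency_at_large_n(self, rng):
        n, p = 5000, 4
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.7, 0.5, 0.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        model = fit_lasso_logistic(X, y, lam=1e-5)
        np.testing.assert_allclose(model.coef[:3], beta[:3], rtol=0.15)
        assert abs(model.coef[3]) < 0.1

    def test_indicator_variable_selected_noise_dropped(self, rng):
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y + 0.05 * rng.normal(size=n), rng.normal(size=(n, 9))])
        Xs = standardize(X)
        lam = lasso_lambda_max(Xs, y) * 0.3
        coef = fit_lasso_logistic(Xs, y, lam).coef
        assert coef[0] != 0
        assert (coef[1:] == 0).all()

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_logistic(np.zeros((4, 2)), np.array([0, 0, 1, 1]), -1.0)


class TestBoruta:
    def test_label_feature_confirmed_across_seeds(self, rng):
        n = 80
        y = np.repeat([0, 1], n // 2)
        for seed in range(6):
            r = np.random.default_rng(seed)
            X = np.column_stack([y + 0.01 * r.normal(size=n), r.normal(size=(n, 20))])
            res = boruta_select(X, y, n_trees=50, alpha=0.01, max_iter=30, seed=seed)
            assert res.decisions[0] == "confirmed", seed

    def test_all_noise_data_confirms_nothing(self):
        n_confirmed = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.normal(size=(60, 20))
            y = np.repeat([0, 1], 30)
            res = boruta_select(X, y, n_trees=30, alpha=0.01, max_iter=20, seed=seed)
            n_confirmed.append((res.decisions == "confirmed").sum())
        assert sum(np.array(n_confirmed) == 0) >= 9

    def test_one_shadow_per_real_feature(self, monkeypatch):
        seen = []
        real_cls = selectors_mod.RandomForestClassifier

        class SpyRF(real_cls):
            def fit(self, X, y):
                seen.append(X.shape[1])
                return super().fit(X, y)

        monkeypatch.setattr(selectors_mod, "RandomForestClassifier", SpyRF)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 7))
        y = np.repeat([0, 1], 20)
        boruta_select(X, y, n_trees=10, max_iter=10, seed=0)
        assert seen[0] == 14  # real + shadow copies in the first iteration

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            boruta_select(np.zeros((20, 3)), np.zeros(20, dtype=int), max_iter=10)
        with pytest.raises(ValueError, match="max_iter"):
            boruta_select(np.zeros((20, 3)), np.repeat([0, 1], 10), max_iter=5)


class TestTuneAndEvaluate:
    def test_hundred_fold_fits_per_grid_point(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        cfg = AnalysisConfig(n_repeats=20, plsda_components=(1, 2))
        perf, _ = tune_and_evaluate("plsda", X, y, seed=0, config=cfg)
        assert perf.n_fold_fits_per_grid_point == 100
        assert perf.n_folds == 5 and perf.n_repeats == 20

    @pytest.mark.parametrize("method", ["plsda", "lasso", "boruta"])
    def test_null_data_scores_near_chance(self, method):
        cfg = AnalysisConfig.reduced()
        bas = []
        for seed in (0, 1, 2):
            m, y = make_null_dataset(100, 85, seed=seed)
            perf, _ = tune_and_evaluate(method, m.values(), y, seed=seed, config=cfg)
            bas.append(perf.balanced_accuracy)
        assert np.mean(bas) == pytest.approx(0.5, abs=0.07)

    @pytest.mark.parametrize("method", ["plsda", "lasso", "boruta"])
    def test_separable_data_scores_high(self, method, rng):
        n, p = 100, 85
        X = rng.normal(size=(n, p))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, :5] += 3.0  # standardized mean shift of 3 on 5 variables
        # enough Boruta iterations that a streaky-but-imperfect hit record can
        # still clear the corrected binomial test
        cfg = AnalysisConfig.reduced(boruta_trees=30, boruta_max_iter=30)
        perf, sel = tune_and_evaluate(method, X, y, seed=3, config=cfg)
        assert perf.balanced_accuracy > 0.9
        assert set(sel.selected) & set(range(5))

    def test_deterministic_given_seed(self, rng):
        m, y = make_null_dataset(60, 10, seed=2)
        cfg = AnalysisConfig.reduced()
        p1, s1 = tune_and_evaluate("lasso", m.values(), y, seed=11, config=cfg)
        p2, s2 = tune_and_evaluate("lasso", m.values(), y, seed=11, config=cfg)
        assert p1.balanced_accuracy == p2.balanced_accuracy
        assert s1.selected == s2.selected

    def test_tiny_class_falls_back_to_leave_pair_out(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.warns(UserWarning, match="leave-pair-out"):
            perf, _ = tune_and_evaluate(
                "plsda", X, y, seed=0, config=AnalysisConfig(n_repeats=1, plsda_components=(1,))
            )
        assert 0.0 <= perf.balanced_accuracy <= 1.0


def test_boruta_deterministic_given_seed(rng):
    X = rng.normal(size=(50, 8))
    y = np.repeat([0, 1], 25)
    a = boruta_select(X, y, n_trees=15, max_iter=12, seed=42)
    b = boruta_select(X, y, n_trees=15, max_iter=12, seed=42)
    assert (a.decisions == b.decisions).all()
    assert (a.hits == b.hits).all()
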