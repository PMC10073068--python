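"""Bootstrap stability, permutation thresholds, flags, and orchestration."""

import numpy as np
import pytest

from solemetab.config import AnalysisConfig
from solemetab.selectors import METHODS
from solemetab.simulate import SimulationConfig, make_null_dataset, simulate_cohort
from solemetab.stability import (
    StabilityReport,
    baseline_thresholds,
    bootstrap_stability,
    flag_informative,
    observed_stability,
    run_full_analysis,
)

FAST = AnalysisConfig.reduced(
    n_repeats=1, lasso_n_lambda=4, plsda_components=(1, 2),
    boruta_trees=5, B_observed=6, n_permutations=2, B_baseline=4,
)


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(8)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=(n, 9))])
    return X, y


class TestBootstrapStability:
    def test_single_resample_gives_zero_or_hundred(self, signal_data):
        X, y = signal_data
        s = bootstrap_stability(X, y, "plsda", B=1, seed=4, config=FAST)
        assert set(np.unique(s)) <= {0.0, 100.0}

    def test_same_seed_same_stabilities(self, signal_data):
        X, y = signal_data
        a = bootstrap_stability(X, y, "lasso", B=10, seed=3, config=FAST)
        b = bootstrap_stability(X, y, "lasso", B=10, seed=3, config=FAST)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("method", METHODS)
    def test_label_identical_variable_is_near_always_selected(self, method, signal_data):
        X, y = signal_data
        cfg = AnalysisConfig.reduced(boruta_trees=20)
        s = bootstrap_stability(X, y, method, B=20, seed=1, config=cfg)
        assert s[0] >= 95.0

    def test_bad_inputs(self, signal_data):
        X, y = signal_data
        with pytest.raises(ValueError):
            bootstrap_stability(X, y, "plsda", B=0, config=FAST)
        with pytest.raises(ValueError):
            bootstrap_stability(X, np.zeros_like(y), "plsda", B=2, config=FAST)
        with pytest.raises(ValueError):
            bootstrap_stability(X, y, "svm", B=2, config=FAST)


class TestObservedStability:
    def test_observed_is_mean_of_three_methods(self, signal_data):
        X, y = signal_data
        out = observed_stability(X, y, B=5, seed=2, config=FAST)
        manual = (out["plsda"] + out["lasso"] + out["boruta"]) / 3
        np.testing.assert_allclose(out["observed"], manual, atol=1e-9)
        assert ((out["observed"] >= 0) & (out["observed"] <= 100)).all()


class TestBaselineThresholds:
    def test_thresholds_are_averaged_percentiles(self, signal_data):
        X, y = signal_data
        t99, t100, baselines = baseline_thresholds(
            X, y, n_permutations=3, B=4, seed=5, config=FAST
        )
        assert t99 == pytest.approx(np.mean(np.percentile(baselines, 99, axis=1)))
        assert t100 == pytest.approx(np.mean(baselines.max(axis=1)))
        assert t100 >= t99

    def test_requires_two_permutations(self, signal_data):
        X, y = signal_data
        with pytest.raises(ValueError):
            baseline_thresholds(X, y, n_permutations=1, B=2, config=FAST)


class TestFlagInformative:
    def _report(self, observed, t99, t100):
        p = len(observed)
        z = np.zeros(p)
        return StabilityReport(
            variables=tuple(f"v{i}" for i in range(p)),
            stability_plsda=z, stability_lasso=z, stability_boruta=z,
            observed=np.asarray(observed, dtype=float), T99=t99, T100=t100,
        )

    def test_both_flags_above_both_thresholds(self):
        r = self._report([95.0, 50.0], 85.0, 90.0)
        above99, above100 = flag_informative(r)
        assert above99 == ["v0"] and above100 == ["v0"]

    def test_boundary_is_strict(self):
        r = self._report([85.0], 85.0, 90.0)
        above99, above100 = flag_informative(r)
        assert above99 == [] and above100 == []

    def test_empty_flag_sets_are_valid(self):
        above99, above100 = flag_informative(self._report([10.0, 20.0], 85.0, 90.0))
        assert above99 == [] and above100 == []

    def test_above_t100_implies_above_t99(self, signal_data):
        X, y = signal_data
        out = observed_stability(X, y, B=5, seed=9, config=FAST)
        t99, t100, _ = baseline_thresholds(X, y, n_permutations=2, B=3, seed=9, config=FAST)
        r = self._report(out["observed"], t99, t100)
        assert set(flag_informative(r)[1]) <= set(flag_informative(r)[0])


class TestRunFullAnalysis:
    @pytest.fixture(scope="class")
    def result(self):
        records, m, cat = simulate_cohort(SimulationConfig(n_animals=300, seed=21))
        return run_full_analysis(m, cat, records, config=FAST, seed=5)

    def test_emits_all_17_subsets(self, result):
        assert len(result.subsets) == 17
        assert sum(sa.report is not None for sa in result.subsets) >= 10

    def test_combined_equals_mean_of_methods(self, result):
        for sa in result.subsets:
            if sa.performances is None:
                continue
            manual = np.mean([sa.performances[m].balanced_accuracy for m in METHODS])
            assert sa.combined_balanced_accuracy == pytest.approx(manual)

    def test_thresholds_ordered_in_every_report(self, result):
        for sa in result.subsets:
            if sa.report is not None:
                assert sa.report.T100 >= sa.report.T99

    def test_tables_have_expected_structure(self, result):
        perf = result.performance_table()
        assert len(perf) == 17
        assert {"ba_plsda", "ba_lasso", "ba_boruta", "ba_combined"} <= set(perf.columns)
        stab = result.stability_table("T99")
        assert {"variable", "log2fc", "observed_stability", "T99", "T100"} <= set(stab.columns)

    def test_matched_controls_balance_cases_overall(self, result):
        # control matching draws one control per case within each parity cohort
        perf = result.performance_table()
        row = perf.loc[
            (perf.time_point == "T3") & (perf.parity == "all") & (perf.outcome == "all_SU")
        ].iloc[0]
        assert row["n_controls"] >= row["n_cases"] * 0.3  # controls shared across outcomes


class TestNullExchangeability:
    def test_permuted_observed_matches_baseline_distribution(self):
        """After permuting the labels, observed stabilities are drawn from the
        same distribution as the baseline stabilities (two-sample KS test)."""
        from scipy import stats

        from solemetab.simulate import make_null_dataset

        cfg = AnalysisConfig.reduced(boruta_trees=5)
        pooled_obs, pooled_base = [], []
        for seed in range(3):
            m, y = make_null_dataset(60, 30, seed=seed)
            X = m.values()
            rng = np.random.default_rng(1000 + seed)
            y_perm = rng.permutation(y)
            obs = observed_stability(X, y_perm, B=10, seed=rng, config=cfg)["observed"]
            _, _, baselines = baseline_thresholds(
                X, y, n_permutations=2, B=10, seed=rng, config=cfg
            )
            pooled_obs.extend(obs)
            pooled_base.extend(baselines.ravel())
        assert stats.ks_2samp(pooled_obs, pooled_base).pvalue > 0.01


def test_observed_stability_nondecreasing_in_effect_size():
    """Holding n and noise fixed, a planted variable's observed stability does
    not decrease as its |log2FC| grows (Monte-Carlo tolerance of one resample
    step)."""
    from solemetab.simulate import make_null_dataset

    cfg = AnalysisConfig.reduced()
    stabs = []
    for log2fc in (0.2, 0.8, 1.5):
        m, y = make_null_dataset(200, 20, seed=14)
        X = m.values().copy()
        X[y == 1, 0] *= 2**log2fc
        out = observed_stability(X, y, B=20, seed=7, config=cfg)
        stabs.append(out["observed"][0])
    assert stabs[1] >= stabs[0] - 5.0
    assert stabs[2] >= stabs[1] - 5.0
    assert stabs[2] > stabs[0]
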