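"""Two-proportion z-test (formula, calibration, cross-check), policy
comparison tables, and gradient-boosting attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsis_safety.hazards import FlagTable
from sepsis_safety.stats import (AttributionReport, StatsError, attribution,
                                 compare_policies, fit_unsafe_classifier,
                                 relative_reduction_percent,
                                 significance_sweep, two_proportion_ztest,
                                 unsafe_rate_percent, ztest_components)


class TestZTest:
    def test_equal_counts_give_z_zero_p_one(self):
        t = two_proportion_ztest(30, 30, 100, sided="two-sided")
        assert t.z == 0.0
        assert t.p_value == pytest.approx(1.0)

    def test_frozen_direct_formula_oracle(self):
        """n=100, x_h=50, x_ai=40: values frozen from an independent
        high-precision evaluation of the pooled-proportion formula."""
        t = two_proportion_ztest(50, 40, 100, sided="one-sided")
        assert t.z == pytest.approx(-1.4213381090374029, abs=1e-12)
        assert t.p_value == pytest.approx(0.07760924484234204, abs=1e-12)
        assert t.p_pooled == pytest.approx(0.45)
        t2 = two_proportion_ztest(50, 40, 100, sided="two-sided")
        assert t2.p_value == pytest.approx(0.15521848968468407, abs=1e-12)

    def test_matches_statsmodels_pooled_test(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for x_h, x_ai, n in [(50, 40, 100), (12, 20, 77), (3, 1, 9)]:
            t = two_proportion_ztest(x_h, x_ai, n, sided="one-sided")
            z_sm, p_sm = statsmodels.proportions_ztest(
                [x_ai, x_h], [n, n], alternative="smaller")
            assert t.z == pytest.approx(z_sm, abs=1e-10)
            assert t.p_value == pytest.approx(p_sm, abs=1e-10)

    @given(x_h=st.integers(0, 50), x_ai=st.integers(0, 50))
    @settings(max_examples=60, deadline=None)
    def test_swapping_counts_negates_z(self, x_h, x_ai):
        z1 = ztest_components(x_h, x_ai, 50)[0]
        z2 = ztest_components(x_ai, x_h, 50)[0]
        assert z1 == -z2 or (np.isinf(z1) and np.isinf(z2) and z1 == -z2)

    @given(factor=st.integers(2, 20))
    @settings(max_examples=20, deadline=None)
    def test_common_scaling_multiplies_z_by_sqrt_factor(self, factor):
        z1 = ztest_components(30, 20, 100)[0]
        zf = ztest_components(30 * factor, 20 * factor, 100 * factor)[0]
        assert zf == pytest.approx(z1 * np.sqrt(factor), rel=1e-12)

    def test_z_sign_matches_proportion_difference(self):
        assert ztest_components(10, 30, 100)[0] > 0
        assert ztest_components(30, 10, 100)[0] < 0

    def test_degenerate_pooled_proportions(self):
        # pooled proportion 0 or 1 forces equal counts, hence z = 0
        assert two_proportion_ztest(0, 0, 50).z == 0.0
        t = two_proportion_ztest(50, 50, 50, sided="two-sided")
        assert t.z == 0.0 and t.p_value == pytest.approx(1.0)
        # maximal disagreement keeps a finite, huge z under the pooled formula
        t_big = two_proportion_ztest(0, 50, 50, sided="one-sided")
        assert t_big.z == pytest.approx(10.0)
        assert t_big.p_value == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            two_proportion_ztest(1, 1, 0)
        with pytest.raises(StatsError):
            two_proportion_ztest(5, 1, 4)
        with pytest.raises(StatsError):
            two_proportion_ztest(1, 1, 10, sided="sideways")


class TestCalibration:
    def test_type_one_error_near_nominal_under_null(self):
        """H0: both agents Bernoulli(0.3), N=500 — two-sided rejection at
        alpha=0.05 over 10,000 replicates lies in [0.04, 0.06]."""
        rng = np.random.default_rng(2024)
        x_h = rng.binomial(500, 0.3, 10_000)
        x_a = rng.binomial(500, 0.3, 10_000)
        z = ztest_components(x_h, x_a, 500)[0]
        rejection = (np.abs(z) > 1.959963984540054).mean()
        assert 0.04 <= rejection <= 0.06

    def test_one_sided_power_exceeds_ninety_percent(self):
        """p_human=0.5 vs p_ai=0.4, N=1000: one-sided rejection rate > 0.9."""
        rng = np.random.default_rng(7)
        x_h = rng.binomial(1000, 0.5, 2000)
        x_a = rng.binomial(1000, 0.4, 2000)
        z = ztest_components(x_h, x_a, 1000)[0]
        assert (z < -1.6448536269514722).mean() > 0.9


class TestComparison:
    def _hand_flags(self):
        n = 10
        df = pd.DataFrame({
            "at_risk_A": [True] * 8 + [False] * 2,
            "unsafe_human_A": [True] * 4 + [False] * 6,
            "unsafe_p_A": [True] * 2 + [False] * 8,
            "unsafe_human_any": [True] * 4 + [False] * 6,
            "unsafe_p_any": [True] * 2 + [False] * 8,
        })
        return FlagTable(df, ["A"], ["human", "p"])

    def test_proportions_equal_hand_ratios(self):
        props, tests = compare_policies(self._hand_flags())
        by = props.set_index("agent")
        assert by.loc["human", "proportion"] == pytest.approx(0.5)
        assert by.loc["p", "proportion"] == pytest.approx(0.25)
        assert tests[("A", "p")].n == 8

    def test_identical_policy_gives_z_zero(self):
        df = pd.DataFrame({
            "at_risk_A": [True] * 6,
            "unsafe_human_A": [True, True, False, False, False, False],
            "unsafe_p_A": [True, True, False, False, False, False],
            "unsafe_human_any": [False] * 6,
            "unsafe_p_any": [False] * 6,
        })
        _, tests = compare_policies(FlagTable(df, ["A"], ["human", "p"]))
        assert tests[("A", "p")].z == 0.0

    def test_ordering_on_planted_cohort(self, prepared_run):
        """Safe <= original <= human in every scenario planted at >= 0.3."""
        props, _ = compare_policies(prepared_run.all_flags)
        piv = props.pivot(index="scenario", columns="agent", values="proportion")
        for sid in ("A", "C", "D"):
            assert piv.loc[sid, "safe"] <= piv.loc[sid, "original"] + 1e-12
            assert piv.loc[sid, "original"] <= piv.loc[sid, "human"] + 1e-12

    def test_rate_helpers(self):
        assert unsafe_rate_percent(50, 100) == 50.0
        assert relative_reduction_percent(100, 88) == pytest.approx(12.0)
        with pytest.raises(StatsError):
            unsafe_rate_percent(1, 0)


class TestSweepSignificance:
    def test_single_threshold_equals_direct_test(self):
        sweep = pd.DataFrame({"map_threshold": [55.0], "N": [100],
                              "x_human": [30], "x_ai": [20]})
        out = significance_sweep(sweep, policy="ai")
        direct = two_proportion_ztest(30, 20, 100)
        assert out["z"][0] == pytest.approx(direct.z)
        assert out["p_value"][0] == pytest.approx(direct.p_value)

    def test_three_thresholds_match_three_direct_calls(self):
        sweep = pd.DataFrame({"map_threshold": [50.0, 55.0, 60.0],
                              "N": [40, 100, 180],
                              "x_human": [20, 30, 40], "x_ai": [10, 20, 30]})
        out = significance_sweep(sweep, policy="ai")
        for i in range(3):
            d = two_proportion_ztest(int(sweep["x_human"][i]),
                                     int(sweep["x_ai"][i]), int(sweep["N"][i]))
            assert out["z"][i] == pytest.approx(d.z)

    def test_zero_n_threshold_recorded_as_undefined(self):
        sweep = pd.DataFrame({"map_threshold": [45.0], "N": [0],
                              "x_human": [0], "x_ai": [0]})
        out = significance_sweep(sweep, policy="ai")
        assert np.isnan(out["z"][0]) and np.isnan(out["p_value"][0])


class TestClassifierAndAttribution:
    def _planted(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{j}" for j in range(5)])
        y = (X["f1"] < 0.2).to_numpy().astype(int)
        return X, y

    def test_separable_signal_learned(self):
        X, y = self._planted()
        model = fit_unsafe_classifier(X.iloc[:600], y[:600], seed=1)
        acc = (model.predict(X.iloc[600:]) == y[600:]).mean()
        assert acc > 0.95

    def test_shuffled_labels_learn_nothing(self):
        X, y = self._planted()
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        model = fit_unsafe_classifier(X.iloc[:600], y_perm[:600], seed=1)
        acc = (model.predict(X.iloc[600:]) == y_perm[600:]).mean()
        prior = max(y_perm[600:].mean(), 1 - y_perm[600:].mean())
        assert abs(acc - prior) < 0.1

    def test_refit_is_deterministic(self):
        X, y = self._planted()
        p1 = fit_unsafe_classifier(X, y, seed=5).predict_proba(X)
        p2 = fit_unsafe_classifier(X, y, seed=5).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        X, _ = self._planted()
        with pytest.raises(StatsError):
            fit_unsafe_classifier(X, np.zeros(len(X)), seed=0)

    def test_planted_feature_ranked_first(self):
        X, y = self._planted(seed=11)
        model = fit_unsafe_classifier(X, y, seed=2)
        report = attribution(model, X)
        assert report.features[0] == "f1"
        assert report.relative[0] == 1.0
        assert (np.diff(report.mean_abs) <= 1e-12).all()   # sorted descending

    def test_null_labels_show_no_dominant_feature(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(600, 6)),
                         columns=[f"f{j}" for j in range(6)])
        y = rng.integers(0, 2, 600)
        model = fit_unsafe_classifier(X, y, seed=4)
        report = attribution(model, X)
        rest_median = np.median(report.mean_abs[1:])
        assert report.mean_abs[0] <= 3.0 * rest_median

    def test_constant_feature_gets_near_zero_attribution(self):
        X, y = self._planted(seed=13)
        X["const"] = 1.0
        model = fit_unsafe_classifier(X, y, seed=6)
        report = attribution(model, X)
        idx = report.features.index("const")
        assert report.mean_abs[idx] == pytest.approx(0.0, abs=1e-8)

    def test_schema_mismatch_rejected(self):
        X, y = self._planted()
        model = fit_unsafe_classifier(X, y, seed=1)
        with pytest.raises(StatsError, match="schema"):
            attribution(model, X.rename(columns={"f1": "g1"}))
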