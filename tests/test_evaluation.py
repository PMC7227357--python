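import numpy as np
import pandas as pd
import pytest

from eq5dval import (
    DUMMY_TERMS,
    ModelSpec,
    ValueSetCoefficients,
    compare_value_sets,
    comparable_pair_count,
    dominates,
    enumerate_all_states,
    export_curve_data,
    logical_error_count,
    predict_all,
    prediction_errors,
)


def naive_logical_errors(tariff: pd.Series) -> int:
    """Double-loop oracle over all 243 x 242 ordered pairs."""
    states = enumerate_all_states()
    count = 0
    for a in states:
        for b in states:
            if dominates(a, b) and tariff[a.label] < tariff[b.label]:
                count += 1
    return count


class TestPredictionErrors:
    @pytest.mark.parametrize("model,method,mae,n05,n10", [
        ("model1", "VAS", 0.0304, 4, 0),
        ("model2", "TTO", 0.0269, 1, 0),
        ("model3", "VAS", 0.0327, 4, 0),
        ("model4", "TTO", 0.0310, 4, 0),
    ])
    def test_published_diagnostics_reproduced(self, table4, observed_means,
                                              model, method, mae, n05, n10):
        """MAE over the 17 non-anchor states and strict threshold counts."""
        errs = prediction_errors(table4[model], observed_means[method])
        assert round(errs.mae, 4) == mae
        assert errs.n_err_gt_005 == n05
        assert errs.n_err_gt_010 == n10

    @pytest.mark.parametrize("model,method,r", [
        ("model1", "VAS", 0.9847), ("model2", "TTO", 0.9879),
        ("model3", "VAS", 0.9813), ("model4", "TTO", 0.9867),
    ])
    def test_published_correlations_reproduced(self, table4, observed_means,
                                               model, method, r):
        """Pearson r between observed means and predictions, 18 states."""
        errs = prediction_errors(table4[model], observed_means[method])
        assert round(errs.r, 4) == r

    def test_perfect_predictions_give_zero_errors(self, table4):
        tariff = predict_all(table4["model3"])
        from eq5dval.health_states import DESIGN_LABELS

        observed = tariff.loc[list(DESIGN_LABELS)]
        errs = prediction_errors(table4["model3"], observed)
        assert errs.mae == 0.0 and errs.n_err_gt_005 == 0 and errs.n_err_gt_010 == 0

    def test_state_order_invariance(self, table4, observed_means):
        a = prediction_errors(table4["model3"], observed_means["VAS"])
        b = prediction_errors(table4["model3"], observed_means["VAS"].iloc[::-1])
        assert a.mae == b.mae and a.r == pytest.approx(b.r)


class TestLogicalErrors:
    def test_published_tariffs_have_zero_errors(self, table4):
        for model in table4.values():
            assert logical_error_count(predict_all(model)) == 0

    def test_comparable_pair_count_combinatorial(self):
        assert comparable_pair_count() == 6 ** 5 - 243 == 7533

    def test_inverted_level_ordering_creates_errors(self):
        beta = {t: -0.2 if t.endswith("3") else -0.1 for t in DUMMY_TERMS}
        beta["MO2"], beta["MO3"] = -0.20, -0.05  # L3 milder than L2
        bad = ValueSetCoefficients(coefficients=beta, spec=ModelSpec(False, False))
        tariff = predict_all(bad)
        n = logical_error_count(tariff)
        assert n > 0
        assert n == naive_logical_errors(tariff)

    def test_matches_naive_oracle_on_random_tariffs(self):
        labels = [s.label for s in enumerate_all_states()]
        rng = np.random.default_rng(2024)
        for _ in range(3):
            tariff = pd.Series(rng.uniform(-1, 1, 243), index=labels)
            assert logical_error_count(tariff) == naive_logical_errors(tariff)

    def test_monotone_additive_tariff_is_error_free(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            l2 = rng.uniform(0.02, 0.15, 5)
            l3 = l2 + rng.uniform(0.01, 0.2, 5)
            beta = {}
            for i, d in enumerate(("MO", "SC", "UA", "PD", "AD")):
                beta[f"{d}2"], beta[f"{d}3"] = -l2[i], -l3[i]
            vs = ValueSetCoefficients(coefficients=beta, spec=ModelSpec(False, False))
            assert logical_error_count(predict_all(vs)) == 0

    def test_incomplete_tariff_rejected(self, table4):
        tariff = predict_all(table4["model3"]).drop("22222")
        with pytest.raises(ValueError, match="243"):
            logical_error_count(tariff)


class TestComparison:
    def test_largest_cross_method_gap_is_pd3(self, table4):
        rep = compare_value_sets(table4["model1"], table4["model2"])
        assert rep.max_abs_dummy_diff == pytest.approx(0.0586, abs=1e-12)
        assert rep.max_abs_dummy_diff_3dp == 0.059
        assert rep.max_term == "PD3"

    def test_self_comparison_is_zero(self, table4):
        rep = compare_value_sets(table4["model3"], table4["model3"])
        assert (rep.term_differences == 0).all()
        assert rep.max_abs_dummy_diff == 0.0
        assert (rep.state_differences == 0).all()

    def test_state_differences_match_elementwise_subtraction(self, table4):
        rep = compare_value_sets(table4["model3"], table4["model4"])
        direct = predict_all(table4["model3"]) - predict_all(table4["model4"])
        pd.testing.assert_series_equal(rep.state_differences, direct)
        assert len(rep.state_differences) == 243


class TestCurveExport:
    def test_single_tariff_sorted_non_increasing(self, table4):
        out = export_curve_data({"m3": predict_all(table4["model3"])})
        v = out["m3"].to_numpy()
        assert len(out) == 243
        assert (np.diff(v) <= 1e-12).all()

    def test_identical_tariffs_give_identical_columns(self, table4):
        t = predict_all(table4["model1"])
        out = export_curve_data({"a": t, "b": t.copy()})
        assert (out["a"] == out["b"]).all()

    def test_cross_module_consistency_with_comparison(self, table4):
        out = export_curve_data({
            "m3": predict_all(table4["model3"]), "m4": predict_all(table4["model4"])})
        rep = compare_value_sets(table4["model3"], table4["model4"])
        diffs = (out["m3"] - out["m4"]).sort_index()
        pd.testing.assert_series_equal(diffs, rep.state_differences.sort_index(),
                                       check_names=False)
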