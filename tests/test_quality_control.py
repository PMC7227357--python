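import numpy as np
import pandas as pd
import pytest

from eq5dval import (
    CohortConfig,
    DUMMY_TERMS,
    ModelSpec,
    QCConfig,
    apply_exclusions,
    count_inconsistencies,
    detect_outliers,
    generate_cohort,
    respondent_sd_flag,
)
from eq5dval.health_states import DESIGN_LABELS, design_states
from eq5dval.quality_control import IncompleteDataError
from eq5dval.valuation_models import design_matrix


def utilities_from_decrements(beta: dict[str, float]) -> pd.Series:
    """Noise-free utilities over the 18 design states implied by positive
    disutility decrements (the inverse of the through-origin fit)."""
    X = design_matrix(list(design_states()), ModelSpec(False, False))
    vec = np.array([beta[t] for t in DUMMY_TERMS])
    return pd.Series(1.0 - X.to_numpy() @ vec, index=X.index)


MONOTONE_BETA = {  # level-ordered, all positive: zero violations by construction
    "MO2": 0.12, "MO3": 0.21, "SC2": 0.11, "SC3": 0.21, "UA2": 0.09,
    "UA3": 0.23, "PD2": 0.08, "PD3": 0.25, "AD2": 0.07, "AD3": 0.20,
}


def swapped(beta: dict[str, float], dims: list[str]) -> dict[str, float]:
    out = dict(beta)
    for d in dims:
        out[f"{d}2"], out[f"{d}3"] = out[f"{d}3"], out[f"{d}2"]
    return out


class TestInconsistencyCount:
    def test_monotone_truth_has_zero_violations(self):
        assert count_inconsistencies(utilities_from_decrements(MONOTONE_BETA)) == 0

    def test_one_swapped_dimension_gives_one_violation(self):
        # mobility L2 decrement 0.21 > L3 decrement 0.12: only b3 > b2 fails
        u = utilities_from_decrements(swapped(MONOTONE_BETA, ["MO"]))
        assert count_inconsistencies(u) == 1

    @pytest.mark.parametrize("n_swaps", [2, 3, 5])
    def test_each_swap_adds_one_violation(self, n_swaps):
        dims = ["MO", "SC", "UA", "PD", "AD"][:n_swaps]
        u = utilities_from_decrements(swapped(MONOTONE_BETA, dims))
        assert count_inconsistencies(u) == n_swaps

    def test_negative_level_effects_count_fully(self):
        beta = dict(MONOTONE_BETA, MO2=-0.05, MO3=-0.10)  # b2<0, b3<b2, b3<0
        assert count_inconsistencies(utilities_from_decrements(beta)) == 3

    def test_ties_count_as_consistent(self):
        beta = dict(MONOTONE_BETA, MO2=0.15, MO3=0.15)
        assert count_inconsistencies(utilities_from_decrements(beta)) == 0

    def test_bounded_by_fifteen(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            u = pd.Series(rng.uniform(-1, 1, 18), index=list(DESIGN_LABELS))
            assert 0 <= count_inconsistencies(u) <= 15

    def test_missing_state_raises(self):
        u = utilities_from_decrements(MONOTONE_BETA).drop("33333")
        with pytest.raises(IncompleteDataError):
            count_inconsistencies(u)


def _one_state_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "respondent_id": [f"r{i}" for i in range(len(values))],
        "state": ["22222"] * len(values),
        "utility": values,
    })


class TestOutlierDetection:
    def test_identical_values_never_flagged(self):
        out = detect_outliers(_one_state_frame(np.full(30, 0.4)))
        assert not out["outlier"].any()

    def test_far_isolated_value_flagged(self):
        base = np.linspace(0.2, 0.6, 29)
        probe = np.concatenate([base, [2.0]])
        q1, q3 = np.percentile(probe, [25, 75])
        iqr = q3 - q1
        values = np.concatenate([base, [q3 + 4 * iqr]])
        out = detect_outliers(_one_state_frame(values))
        assert out["outlier"].sum() == 1
        assert out.loc[out["outlier"], "utility"].iloc[0] == pytest.approx(q3 + 4 * iqr)

    def test_value_at_exactly_three_iqr_not_flagged(self):
        base = np.linspace(0.2, 0.6, 29)
        probe = np.concatenate([base, [2.0]])
        q1, q3 = np.percentile(probe, [25, 75])
        iqr = q3 - q1
        values = np.concatenate([base, [q3 + 3 * iqr]])  # strict inequality boundary
        out = detect_outliers(_one_state_frame(values))
        assert not out["outlier"].any()

    def test_too_few_respondents_raises(self):
        with pytest.raises(IncompleteDataError):
            detect_outliers(_one_state_frame(np.linspace(0, 1, 10)))


class TestSdFlag:
    def test_sd_exactly_on_target(self):
        v = np.arange(18, dtype=float)
        v *= 2.5 / np.std(v, ddof=1)
        assert respondent_sd_flag(v)

    def test_constant_values_fail(self):
        assert not respondent_sd_flag(np.full(18, 4.0))

    def test_sd_too_large_fails(self):
        v = np.arange(18, dtype=float)
        v *= 3.1 / np.std(v, ddof=1)
        assert not respondent_sd_flag(v)


def _replace_respondent(responses: pd.DataFrame, rid: str, utilities: pd.Series) -> pd.DataFrame:
    """Overwrite one respondent's raw responses (both methods) with the raw
    values implied by the given utilities."""
    df = responses.copy()
    for method in ("VAS", "TTO"):
        for state, u in utilities.items():
            mask = (df["respondent_id"] == rid) & (df["method"] == method) & (df["state"] == state)
            if method == "VAS":
                df.loc[mask, "raw"] = 10.0 * u
            else:
                df.loc[mask, "raw"] = 10.0 * abs(u)
                df.loc[mask, "direction"] = "BTD" if u >= 0 else "WTD"
    return df


@pytest.fixture(scope="module")
def base():
    cfg = CohortConfig(n_respondents=30, seed=77)
    responses, _ = generate_cohort(cfg)
    return responses


class TestExclusionCascade:
    def test_missing_state_excludes_as_incomplete(self, base):
        rid = "R0001"
        dropped = base[~((base["respondent_id"] == rid) & (base["state"] == "22222")
                         & (base["method"] == "VAS"))]
        _, report = apply_exclusions(dropped)
        row = report.set_index("respondent_id").loc[rid]
        assert not row["complete"]
        assert row["excluded"] and "incomplete" in row["reasons"]

    def test_exactly_four_inconsistencies_retained_five_excluded(self, base):
        rid = "R0001"
        four = utilities_from_decrements(swapped(MONOTONE_BETA, ["MO", "SC", "UA", "PD"]))
        five = utilities_from_decrements(swapped(MONOTONE_BETA, ["MO", "SC", "UA", "PD", "AD"]))
        _, rep4 = apply_exclusions(_replace_respondent(base, rid, four))
        _, rep5 = apply_exclusions(_replace_respondent(base, rid, five))
        row4 = rep4.set_index("respondent_id").loc[rid]
        row5 = rep5.set_index("respondent_id").loc[rid]
        assert row4["inconsistency_count_vas"] == 4 and not row4["excluded"]
        assert row5["inconsistency_count_vas"] == 5 and row5["excluded"]
        assert "inconsistent" in row5["reasons"]

    def test_monotone_in_thresholds(self, base):
        cfg = CohortConfig(n_respondents=40, seed=88, fraction_incomplete=0.1,
                           fraction_inconsistent=0.1, fraction_outlier=0.1)
        responses, _ = generate_cohort(cfg)
        _, strict = apply_exclusions(responses, QCConfig())
        _, loose = apply_exclusions(responses, QCConfig(max_inconsistencies=8, max_outliers=6))
        excluded_strict = set(strict.loc[strict["excluded"], "respondent_id"])
        excluded_loose = set(loose.loc[loose["excluded"], "respondent_id"])
        assert excluded_loose <= excluded_strict

    def test_report_invariant_to_row_order(self, base):
        shuffled = base.sample(frac=1.0, random_state=0).reset_index(drop=True)
        _, rep_a = apply_exclusions(base)
        _, rep_b = apply_exclusions(shuffled)
        pd.testing.assert_frame_equal(rep_a, rep_b)

    def test_cascade_removes_injected_contamination(self):
        """Quota-injected incomplete respondents are exactly the incompleteness
        exclusions; every injected outlier respondent is excluded."""
        cfg = CohortConfig(n_respondents=60, seed=42, intercept_sd=0.05,
                           noise_sd=0.05, fraction_incomplete=0.1,
                           fraction_inconsistent=0.1, fraction_outlier=0.1)
        responses, profiles = generate_cohort(cfg)
        clean, report = apply_exclusions(responses)
        rep = report.set_index("respondent_id")
        arch = profiles.set_index("respondent_id")["archetype"]
        injected_incomplete = set(arch[arch == "incomplete"].index)
        injected_outlier = set(arch[arch == "outlier"].index)
        flagged_incomplete = set(rep[rep["reasons"].str.contains("incomplete")].index)
        assert flagged_incomplete == injected_incomplete
        excluded = set(rep[rep["excluded"]].index)
        assert injected_outlier <= excluded
        clean_arch = set(arch[arch == "clean"].index)
        assert not (clean_arch & excluded)
        assert set(clean["respondent_id"]) == set(rep.index) - excluded
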