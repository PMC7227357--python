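import pytest

from eq5dval import CohortConfig, generate_cohort, load_fixture


@pytest.fixture(scope="session")
def table4():
    """The four published coefficient columns as ValueSetCoefficients."""
    return load_fixture("table4_coefficients")


@pytest.fixture(scope="session")
def observed_means():
    """Observed per-state mean utilities by method (18 states each)."""
    summary, totals = load_fixture("table3_summary")
    return {
        m: summary.xs(m, level="method")["mean"].astype(float)
        for m in ("VAS", "TTO")
    }


@pytest.fixture(scope="session")
def observed_summary():
    summary, totals = load_fixture("table3_summary")
    return summary, totals


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-respondent clean cohort shared by tests that only need shape."""
    cfg = CohortConfig(n_respondents=40, seed=123)
    responses, profiles = generate_cohort(cfg)
    return cfg, responses, profiles


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Degenerate generator: utilities equal the true tariff exactly."""
    cfg = CohortConfig(
        n_respondents=25, seed=9, intercept_sd=0.0, noise_sd=0.0,
        vas_grid=0.0, tto_grid=0.0,
    )
    responses, profiles = generate_cohort(cfg)
    return cfg, responses, profiles
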