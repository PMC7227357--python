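"""Model evaluation: errors against observed state means, logical-error
scanning of full tariffs, and cross-model comparison.

Conventions that matter here (and reproduce the published diagnostics):

* MAE averages the absolute observed-minus-predicted errors over the 17
  NON-anchor design states; the anchor is predicted exactly 1 and its error
  is identically 0, so including it would only dilute the average.
* The error-count thresholds (> 0.05, > 0.1) are strict and also run over
  the 17 non-anchor states.
* Pearson r between observed means and predictions uses all 18 states
  (anchor included).
* A logical error is an ordered state pair (a, b) where a dominates b but the
  tariff values a strictly below b; exact ties are not errors. Over 243
  states there are 6^5 - 243 = 7533 comparable ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .health_states import FULL_HEALTH_LABEL, enumerate_all_states
from .valuation_models import DUMMY_TERMS, ValueSetCoefficients, predict_all

__all__ = [
    "PredictionErrors",
    "ComparisonReport",
    "prediction_errors",
    "logical_error_count",
    "comparable_pair_count",
    "compare_value_sets",
    "export_curve_data",
]


@dataclass(frozen=True)
class PredictionErrors:
    """Observed-vs-predicted diagnostics for one fitted or transcribed model."""

    mae: float
    n_err_gt_005: int
    n_err_gt_010: int
    r: float
    per_state_error: pd.Series

    def __post_init__(self) -> None:
        assert 0 <= self.n_err_gt_010 <= self.n_err_gt_005 <= 17


def prediction_errors(
    c: ValueSetCoefficients, observed_means: pd.Series
) -> PredictionErrors:
    """MAE, strict threshold counts and Pearson r against observed means.

    ``observed_means`` maps the 18 design-state labels to mean utilities.
    """
    labels = list(observed_means.index)
    if FULL_HEALTH_LABEL not in labels or len(labels) != 18:
        raise ValueError("observed means must cover exactly the 18 design states")
    tariff = predict_all(c)
    pred = tariff.loc[labels]
    err = (observed_means.astype(float) - pred).abs()
    non_anchor = err.drop(FULL_HEALTH_LABEL)
    mae = float(non_anchor.mean())
    r = float(pearsonr(observed_means.astype(float), pred)[0])
    return PredictionErrors(
        mae=mae,
        n_err_gt_005=int((non_anchor > 0.05).sum()),
        n_err_gt_010=int((non_anchor > 0.10).sum()),
        r=r,
        per_state_error=err,
    )


def _levels_matrix() -> np.ndarray:
    return np.array([s.levels for s in enumerate_all_states()], dtype=np.int8)


def _dominance_matrix() -> np.ndarray:
    """Boolean 243x243 matrix: entry (i, j) true iff state i dominates j."""
    L = _levels_matrix()
    le = (L[:, None, :] <= L[None, :, :]).all(axis=2)
    eq = (L[:, None, :] == L[None, :, :]).all(axis=2)
    return le & ~eq


def comparable_pair_count() -> int:
    """Number of ordered dominance-comparable pairs among the 243 states."""
    return int(_dominance_matrix().sum())


def logical_error_count(tariff: pd.Series) -> int:
    """Count dominance violations in a full 243-state tariff.

    ``tariff`` maps every state label to its predicted utility. A violation is
    a pair (a dominates b) with tariff[a] strictly below tariff[b].
    """
    labels = [s.label for s in enumerate_all_states()]
    if set(tariff.index) != set(labels):
        raise ValueError("tariff must cover all 243 states")
    u = tariff.loc[labels].to_numpy(dtype=float)
    dom = _dominance_matrix()
    worse = u[:, None] < u[None, :]
    return int((dom & worse).sum())


@dataclass(frozen=True)
class ComparisonReport:
    """Coefficient- and tariff-level differences between two value sets."""

    term_differences: pd.Series        # signed, a minus b, dummy terms only
    max_abs_dummy_diff: float
    max_abs_dummy_diff_3dp: float
    max_term: str
    state_differences: pd.Series       # a minus b over all 243 states
    tariff_correlation: float


def compare_value_sets(
    a: ValueSetCoefficients, b: ValueSetCoefficients
) -> ComparisonReport:
    """Compare two value sets sharing the same active dummy terms.

    The headline number is the maximum absolute difference over the 10 level
    dummies (constant and N3 excluded), reported raw and at 3 decimals.
    """
    if set(DUMMY_TERMS) - set(a.coefficients) or set(DUMMY_TERMS) - set(b.coefficients):
        raise ValueError("both value sets must carry all 10 dummy terms")
    diffs = pd.Series(
        {t: float(a.coefficients[t]) - float(b.coefficients[t]) for t in DUMMY_TERMS}
    )
    max_term = diffs.abs().idxmax()
    max_abs = float(diffs.abs().max())
    ta, tb = predict_all(a), predict_all(b)
    state_diff = ta - tb
    return ComparisonReport(
        term_differences=diffs,
        max_abs_dummy_diff=max_abs,
        max_abs_dummy_diff_3dp=round(max_abs, 3),
        max_term=str(max_term),
        state_differences=state_diff,
        tariff_correlation=float(pearsonr(ta, tb)[0]),
    )


def export_curve_data(tariffs: dict[str, pd.Series]) -> pd.DataFrame:
    """Ordered series for overlay plots: states sorted by the first tariff.

    Returns a 243-row frame, one column per tariff, sorted by the first
    tariff's predicted value in decreasing order (ties broken by label).
    """
    if not tariffs:
        raise ValueError("at least one tariff is required")
    names = list(tariffs)
    first = tariffs[names[0]]
    order = first.sort_index().sort_values(ascending=False, kind="mergesort").index
    out = pd.DataFrame({name: t.loc[order] for name, t in tariffs.items()})
    out.index.name = "state"
    return out
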