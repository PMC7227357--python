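"""Respondent screening: logical-inconsistency counting, three-criterion
outlier detection, the SD-near-2.5 flag, and the exclusion cascade.

A respondent is excluded when any of the following holds:

1. they did not value all 18 design states under both methods;
2. more than ``max_inconsistencies`` (default 4) of the 15 required level
   orderings fail in either method;
3. they produced more than ``max_outliers`` (default 2) outlying values,
   summed over both methods.

Inconsistencies are judged on the respondent's *implied* level effects: a
10-dummy through-origin regression of their 18 disutilities gives per-
dimension level-2 and level-3 decrements, and each dimension must satisfy
b2 >= 0, b3 >= b2 and b3 >= 0 (3 orderings x 5 dimensions = 15 comparable
pairs; exact ties count as consistent because coarse response grids make them
common). A value is an outlier only if, within its state's cross-respondent
distribution, it simultaneously (1) lies strictly beyond the 1.5*IQR Tukey
fence, (2) sits strictly more than 3*IQR from the nearest quartile, and
(3) falls strictly below the 5th or above the 95th percentile.

The SD flag (|SD of the 18 raw-scale values - 2.5| < 0.5, an interactive
feedback rule during data collection) is reported but never excludes anyone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .elicitation import METHODS, add_utilities, to_disutility
from .health_states import design_states
from .valuation_models import ModelSpec, design_matrix

__all__ = [
    "QCConfig",
    "count_inconsistencies",
    "detect_outliers",
    "respondent_sd_flag",
    "apply_exclusions",
    "MIN_RESPONDENTS_FOR_OUTLIERS",
]

#: Outlier percentiles need a minimally populated cross-respondent sample.
MIN_RESPONDENTS_FOR_OUTLIERS = 20


@dataclass(frozen=True)
class QCConfig:
    max_inconsistencies: int = 4   # exclusion when exceeded
    max_outliers: int = 2          # exclusion when exceeded
    sd_target: float = 2.5         # raw -10..10 scale
    sd_tolerance: float = 0.5
    whisker_multiplier: float = 1.5
    isolation_multiplier: float = 3.0
    percentile_bounds: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        numeric = (self.max_inconsistencies, self.max_outliers, self.sd_target,
                   self.sd_tolerance, self.whisker_multiplier,
                   self.isolation_multiplier, *self.percentile_bounds)
        if any(v < 0 for v in numeric):
            raise ValueError("all QC thresholds must be >= 0")


class IncompleteDataError(ValueError):
    """A respondent is missing design states required for the check."""


# precomputed once: the 18x10 dummy design and its pseudoinverse
_DESIGN = design_states()
_X10 = design_matrix(list(_DESIGN), ModelSpec(False, False)).to_numpy()
_PINV10 = np.linalg.pinv(_X10)


def count_inconsistencies(utilities: pd.Series) -> int:
    """Number of failed level orderings (0..15) for one respondent + method.

    ``utilities`` maps the 18 design-state labels to that respondent's
    utilities. The respondent's own 10-dummy through-origin fit supplies the
    implied decrements; strict reversals count, exact ties do not.
    """
    labels = list(_DESIGN.labels)
    try:
        u = utilities.loc[labels].to_numpy(dtype=float)
    except KeyError as e:
        raise IncompleteDataError(f"missing design state(s): {e}") from e
    if np.isnan(u).any():
        raise IncompleteDataError("missing utility values for some design states")
    beta = _PINV10 @ to_disutility(u)  # positive = utility loss
    violations = 0
    for d in range(5):
        b2, b3 = beta[2 * d], beta[2 * d + 1]
        violations += int(b2 < 0.0) + int(b3 < b2) + int(b3 < 0.0)
    return violations


def detect_outliers(utilities: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Flag outlying values within each state's cross-respondent distribution.

    ``utilities`` must carry columns (respondent_id, state, utility) for ONE
    method. Returns the input plus a boolean ``outlier`` column. Quartiles and
    percentiles use linear interpolation between closest ranks.
    """
    df = utilities.copy()
    counts = df.groupby("state")["utility"].size()
    if (counts < MIN_RESPONDENTS_FOR_OUTLIERS).any():
        small = counts[counts < MIN_RESPONDENTS_FOR_OUTLIERS].index.tolist()
        raise IncompleteDataError(
            f"outlier detection needs >= {MIN_RESPONDENTS_FOR_OUTLIERS} "
            f"respondents per state; too few for {small}"
        )
    lo_p, hi_p = cfg.percentile_bounds
    flags = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("state").groups.items():
        v = df.loc[idx, "utility"].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25.0, 75.0])
        iqr = q3 - q1
        p_lo, p_hi = np.percentile(v, [lo_p, hi_p])
        beyond_fence = (v < q1 - cfg.whisker_multiplier * iqr) | (
            v > q3 + cfg.whisker_multiplier * iqr)
        dist = np.where(v < q1, q1 - v, np.where(v > q3, v - q3, 0.0))
        isolated = dist > cfg.isolation_multiplier * iqr
        extreme = (v < p_lo) | (v > p_hi)
        flags[df.index.get_indexer(idx)] = beyond_fence & isolated & extreme
    out = df.copy()
    out["outlier"] = flags
    return out


def respondent_sd_flag(raw_values: Iterable[float], cfg: QCConfig = QCConfig()) -> bool:
    """True iff the sample SD of the 18 raw-scale values is within 0.5 of 2.5.

    Used during collection as a plausibility signal (a respondent spreading
    values over the -10..10 scale produces an SD near 2.5); reported only.
    """
    v = np.asarray(list(raw_values), dtype=float)
    sd = float(np.std(v, ddof=1))
    return abs(sd - cfg.sd_target) < cfg.sd_tolerance


def apply_exclusions(
    responses: pd.DataFrame, cfg: QCConfig = QCConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the exclusion cascade; returns (surviving responses, QC report).

    Exclusion applies to the respondent as a whole (both methods). The report
    has one row per respondent: completeness, per-method inconsistency counts,
    total outlier count, per-method SD flags, the decision and its reasons.
    """
    df = add_utilities(responses)
    labels = set(_DESIGN.labels)
    respondents = sorted(df["respondent_id"].unique())

    complete: dict[str, bool] = {}
    incon: dict[str, dict[str, float]] = {m: {} for m in METHODS}
    sd_ok: dict[str, dict[str, bool]] = {m: {} for m in METHODS}
    for (rid, method), grp in df.groupby(["respondent_id", "method"]):
        has_all = set(grp["state"]) == labels and len(grp) == 18
        complete[rid] = complete.get(rid, True) and has_all
        if has_all:
            series = grp.set_index("state")["utility"]
            incon[method][rid] = count_inconsistencies(series)
            sd_ok[method][rid] = respondent_sd_flag(10.0 * series.to_numpy(), cfg)
    for rid in respondents:
        for m in METHODS:
            if rid not in incon[m]:
                complete[rid] = False

    # outliers per (respondent, state), separately per method, summed over both
    outlier_count = {rid: 0 for rid in respondents}
    for m in METHODS:
        sub = df[df["method"] == m][["respondent_id", "state", "utility"]]
        if len(sub) == 0:
            continue
        flagged = detect_outliers(sub, cfg)
        per_resp = flagged[flagged["outlier"]].groupby("respondent_id").size()
        for rid, k in per_resp.items():
            outlier_count[rid] += int(k)

    records = []
    for rid in respondents:
        reasons = []
        if not complete[rid]:
            reasons.append("incomplete")
        else:
            if any(incon[m][rid] > cfg.max_inconsistencies for m in METHODS):
                reasons.append("inconsistent")
        if outlier_count[rid] > cfg.max_outliers:
            reasons.append("outlier")
        records.append({
            "respondent_id": rid,
            "complete": complete[rid],
            "inconsistency_count_vas": incon["VAS"].get(rid, np.nan),
            "inconsistency_count_tto": incon["TTO"].get(rid, np.nan),
            "outlier_count": outlier_count[rid],
            "sd_ok_vas": sd_ok["VAS"].get(rid, False),
            "sd_ok_tto": sd_ok["TTO"].get(rid, False),
            "excluded": bool(reasons),
            "reasons": ";".join(reasons),
        })
    report = pd.DataFrame.from_records(records)
    excluded = set(report.loc[report["excluded"], "respondent_id"])
    clean = responses[~responses["respondent_id"].isin(excluded)].reset_index(drop=True)
    return clean, report
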