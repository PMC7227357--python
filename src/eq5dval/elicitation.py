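"""Elicitation transforms between raw VAS / TTO responses and utilities.

Both methods are anchored on the same -1 ~ 0 ~ 1 utility scale: -1 is the
worst imaginable state, 0 is dead, 1 is full health.

* VAS: the respondent marks a state at x on a -10..10 thermometer scale;
  utility = x / 10.
* TTO: over a 10-year horizon, a better-than-death (BTD) state judged
  equivalent to t years of full health gets utility t / 10; a worse-than-death
  (WTD) state where t years of full health compensate 10 - t years in the
  state gets utility -t / 10.

Disutility (1 - utility) is the dependent variable of the value-set models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "METHOD_VAS",
    "METHOD_TTO",
    "METHODS",
    "BTD",
    "WTD",
    "RESPONSE_COLUMNS",
    "vas_to_utility",
    "utility_to_vas",
    "tto_to_utility",
    "utility_to_tto",
    "to_disutility",
    "snap_to_grid",
    "add_utilities",
]

METHOD_VAS = "VAS"
METHOD_TTO = "TTO"
METHODS = (METHOD_VAS, METHOD_TTO)

BTD = "BTD"  # better than death
WTD = "WTD"  # worse than death

#: Canonical respondent-level response schema. ``raw`` is the VAS mark x for
#: VAS rows and the traded years t for TTO rows; ``direction`` is empty for
#: VAS and BTD/WTD for TTO.
RESPONSE_COLUMNS = ("respondent_id", "method", "state", "raw", "direction")


def vas_to_utility(x: float) -> float:
    """Utility of a VAS mark x on the -10..10 scale: x / 10."""
    x = float(x)
    if not -10.0 <= x <= 10.0:
        raise ValueError(f"VAS mark must lie in [-10, 10], got {x}")
    return x / 10.0


def utility_to_vas(u: float) -> float:
    """Inverse VAS transform: the mark 10 * u."""
    u = float(u)
    if not -1.0 <= u <= 1.0:
        raise ValueError(f"utility must lie in [-1, 1], got {u}")
    return 10.0 * u


def tto_to_utility(t: float, direction: str) -> float:
    """Utility of a TTO indifference point: t/10 for BTD, -t/10 for WTD."""
    t = float(t)
    if not 0.0 <= t <= 10.0:
        raise ValueError(f"traded years must lie in [0, 10], got {t}")
    if direction == BTD:
        return t / 10.0
    if direction == WTD:
        return -t / 10.0
    raise ValueError(f"direction must be {BTD!r} or {WTD!r}, got {direction!r}")


def utility_to_tto(u: float) -> tuple[float, str]:
    """Inverse TTO transform: (t, direction) with t = 10|u|.

    Zero maps to (0, BTD): the dead point is reached from the BTD branch.
    """
    u = float(u)
    if not -1.0 <= u <= 1.0:
        raise ValueError(f"utility must lie in [-1, 1], got {u}")
    return (10.0 * abs(u), BTD if u >= 0.0 else WTD)


def to_disutility(u):
    """Disutility 1 - u, the dependent variable of the regressions.

    Accepts scalars or arrays. The map is its own inverse, so it also converts
    disutilities back to utilities; inputs may therefore span [-1, 2] (the
    union of the utility and disutility ranges).
    """
    arr = np.asarray(u, dtype=float)
    if np.any(arr < -1.0) or np.any(arr > 2.0):
        raise ValueError("values must lie in [-1, 2] (utility or disutility range)")
    out = 1.0 - arr
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


def snap_to_grid(u: float, grid: float) -> float:
    """Snap a utility to the nearest multiple of ``grid`` and clamp to [-1, 1].

    Ties round half-away-from-zero, keeping the rule symmetric about the dead
    anchor at 0. ``grid`` must be positive; the function is idempotent.
    """
    if grid <= 0.0:
        raise ValueError(f"grid step must be positive, got {grid}")
    u = float(u)
    snapped = np.sign(u) * np.floor(abs(u) / grid + 0.5) * grid
    return float(min(1.0, max(-1.0, snapped)))


def add_utilities(responses: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a response table with a ``utility`` column.

    VAS rows use x/10; TTO rows use +-t/10 according to their direction.
    """
    df = responses.copy()
    raw = df["raw"].astype(float).to_numpy()
    method = df["method"].to_numpy()
    direction = df["direction"].fillna("").to_numpy() if "direction" in df else np.full(len(df), "")
    util = np.empty(len(df), dtype=float)
    is_vas = method == METHOD_VAS
    util[is_vas] = raw[is_vas] / 10.0
    is_tto = method == METHOD_TTO
    sign = np.where(direction[is_tto] == WTD, -1.0, 1.0)
    util[is_tto] = sign * raw[is_tto] / 10.0
    unknown = ~(is_vas | is_tto)
    if unknown.any():
        bad = sorted(set(method[unknown]))
        raise ValueError(f"unknown elicitation method(s): {bad}")
    if np.any(util < -1.0) or np.any(util > 1.0):
        raise ValueError("raw responses imply utilities outside [-1, 1]")
    df["utility"] = util
    return df
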