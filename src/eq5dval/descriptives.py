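"""Per-state descriptive statistics of elicited utilities.

Mirrors the observed-summary table of a valuation study: per-state n, mean,
sample SD and quartiles; the grand ("Total") mean and SD; and the shares of
better-than-death vs worse-than-death values. Percentiles use linear
interpolation between closest ranks (shared convention with the QC module).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .elicitation import add_utilities
from .health_states import design_states

__all__ = ["summarize_states", "grand_summary", "btd_wtd_shares"]


def _utility_frame(table: pd.DataFrame, method: str | None) -> pd.DataFrame:
    df = table.copy()
    if "utility" not in df.columns:
        df = add_utilities(df)
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    return df


def summarize_states(table: pd.DataFrame, method: str | None = None) -> pd.DataFrame:
    """Per-design-state n, mean, sample SD (n-1) and interpolated quartiles.

    ``table`` is a response or utility table; rows for states outside the
    design are ignored, and every design state must be present.
    """
    df = _utility_frame(table, method)
    labels = list(design_states().labels)
    df = df[df["state"].isin(labels)]
    missing = set(labels) - set(df["state"])
    if missing:
        raise ValueError(f"no observations for design state(s): {sorted(missing)}")
    g = df.groupby("state")["utility"]
    out = pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "sd": g.std(ddof=1),
        "p25": g.quantile(0.25),
        "p50": g.quantile(0.50),
        "p75": g.quantile(0.75),
    })
    return out.reindex(labels).rename_axis("state")


def grand_summary(data) -> tuple[float, float]:
    """Overall (mean, SD) across all values.

    Accepts either a raw utility/response table, or a per-state summary frame
    (as from :func:`summarize_states`). Via the summary path the design must
    be balanced (equal n per state): then the grand mean is the unweighted
    mean of state means, and the SD is pooled from the within- and between-
    state pieces.
    """
    if isinstance(data, pd.DataFrame) and {"mean", "sd", "n"} <= set(data.columns):
        n = data["n"].to_numpy(dtype=float)
        if not np.all(n == n[0]):
            raise ValueError("grand summary from state summaries requires equal n per state")
        m = data["mean"].to_numpy(dtype=float)
        sd = data["sd"].to_numpy(dtype=float)
        grand_mean = float(m.mean())
        n_tot = float(n.sum())
        ss = float(np.sum((n - 1) * sd ** 2 + n * (m - grand_mean) ** 2))
        grand_sd = float(np.sqrt(ss / (n_tot - 1))) if n_tot > 1 else 0.0
        return grand_mean, grand_sd
    df = _utility_frame(pd.DataFrame(data), None)
    u = df["utility"].to_numpy(dtype=float)
    return float(u.mean()), float(u.std(ddof=1))


def btd_wtd_shares(table: pd.DataFrame, method: str | None = None):
    """Better-than-death share (utility >= 0) overall and WTD counts per state.

    Returns (btd_share, wtd_share, per_state) where per_state maps each state
    to its count of negative values. Zero counts as BTD: the dead point is
    reached from the better-than-death elicitation branch.
    """
    df = _utility_frame(table, method)
    u = df["utility"].to_numpy(dtype=float)
    n = len(u)
    if n == 0:
        return np.nan, np.nan, pd.Series(dtype=int)
    wtd = u < 0.0
    per_state = df.loc[wtd].groupby("state").size().reindex(
        sorted(df["state"].unique()), fill_value=0)
    return float((~wtd).mean()), float(wtd.mean()), per_state
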