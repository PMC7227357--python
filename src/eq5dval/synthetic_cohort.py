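"""Synthetic valuation cohort: respondent-level VAS and TTO response tables
with the statistical structure the downstream analysis assumes.

Each respondent values the 18 design states twice (once per method). A
respondent's utility for a state is

    snap( tariff prediction + random intercept + noise )

with the 11111 anchor pinned at exactly 1 (the protocol fixes it). Raw
responses are obtained by inverting the elicitation transforms: a VAS mark
x = 10u, or a TTO trade t = 10|u| with a WTD flag exactly when u < 0.

Controlled contamination for exercising quality control:

* ``incomplete`` respondents drop 1–3 non-anchor states from one method;
* ``inconsistent`` respondents have one randomly chosen dimension's level-2
  and level-3 decrements swapped before sampling (their implied level
  ordering is reversed on that dimension);
* ``outlier`` respondents have 3 of their non-anchor values shifted toward
  the opposite sign by 4*noise_sd + 0.5, which places them far outside the
  cross-respondent distribution of those states.

Archetypes are assigned by quota from a seeded permutation, so realised
contamination counts match the configured fractions exactly. All randomness
derives from a single root seed, drawn in a fixed order (profiles first, then
per-respondent responses in respondent order), so equal seeds give identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .elicitation import (
    BTD,
    METHOD_TTO,
    METHOD_VAS,
    METHODS,
    WTD,
    snap_to_grid,
)
from .health_states import design_states
from .valuation_models import (
    DUMMY_TERMS,
    ValueSetCoefficients,
    predict_state,
)

__all__ = ["CohortConfig", "RespondentProfile", "generate_cohort", "truth_table",
           "default_true_coefficients"]

ARCHETYPES = ("clean", "incomplete", "inconsistent", "outlier")


def default_true_coefficients() -> dict[str, ValueSetCoefficients]:
    """Per-method true tariffs: the published 10-dummy VAS and TTO columns."""
    from .io import load_fixture  # local import: io depends on this module's types

    fx = load_fixture("table4_coefficients")
    return {METHOD_VAS: fx["model3"], METHOD_TTO: fx["model4"]}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the generator.

    Defaults emulate the analysed study sample: 313 respondents x 18 states
    x 2 methods, respondent heterogeneity tau = 0.10 and response noise
    sigma_e = 0.15 (utility units, chosen to land per-state SDs in the
    0.13–0.25 range of the observed summaries), integer VAS marks (utility
    grid 0.1), TTO refined to 0.1 years, no contamination.
    """

    n_respondents: int = 313
    true_coefficients: Mapping[str, ValueSetCoefficients] | None = None
    intercept_sd: float = 0.10
    noise_sd: float = 0.15
    vas_grid: float = 0.1  # utility-scale step (0.1 = integer marks on -10..10); <= 0 disables
    tto_grid: float = 0.1  # years-scale step for the traded time t; <= 0 disables
    fraction_incomplete: float = 0.0
    fraction_inconsistent: float = 0.0
    fraction_outlier: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.intercept_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        fracs = (self.fraction_incomplete, self.fraction_inconsistent,
                 self.fraction_outlier)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("contamination fractions must lie in [0,1] and sum to <= 1")

    def resolved_truth(self) -> dict[str, ValueSetCoefficients]:
        if self.true_coefficients is None:
            return default_true_coefficients()
        return dict(self.true_coefficients)


@dataclass(frozen=True)
class RespondentProfile:
    id: str
    archetype: str
    random_intercept: float


def _swap_dimension(c: ValueSetCoefficients, dim_index: int) -> ValueSetCoefficients:
    """Swap the level-2 and level-3 decrements of one dimension (0..4)."""
    t2, t3 = DUMMY_TERMS[2 * dim_index], DUMMY_TERMS[2 * dim_index + 1]
    coefs = dict(c.coefficients)
    coefs[t2], coefs[t3] = coefs[t3], coefs[t2]
    return replace(c, coefficients=coefs)


def truth_table(cfg: CohortConfig) -> pd.DataFrame:
    """The noise-free design-state utilities implied by the true tariffs."""
    truth = cfg.resolved_truth()
    design = design_states()
    rows = {}
    for method, coefs in truth.items():
        rows[method] = [1.0 if s.label == "11111" else predict_state(coefs, s)
                        for s in design]
    return pd.DataFrame(rows, index=list(design.labels)).rename_axis("state")


def _quota(n: int, fraction: float) -> int:
    return int(round(n * fraction))


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (responses, profiles) for one cohort.

    responses: columns (respondent_id, method, state, raw, direction), one row
    per respondent x method x design state (minus the states dropped by
    incomplete respondents). profiles: (respondent_id, archetype,
    random_intercept).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.resolved_truth()
    missing = [m for m in METHODS if m not in truth]
    if missing:
        raise ValueError(f"true_coefficients missing method(s): {missing}")
    design = design_states()
    labels = list(design.labels)
    non_anchor = labels[1:]

    ids = [f"R{i + 1:04d}" for i in range(cfg.n_respondents)]
    # archetype quotas on a seeded permutation
    n_inc = _quota(cfg.n_respondents, cfg.fraction_incomplete)
    n_swp = _quota(cfg.n_respondents, cfg.fraction_inconsistent)
    n_out = _quota(cfg.n_respondents, cfg.fraction_outlier)
    if n_inc + n_swp + n_out > cfg.n_respondents:
        raise ValueError("contamination quotas exceed the cohort size")
    perm = rng.permutation(cfg.n_respondents)
    archetype = np.full(cfg.n_respondents, "clean", dtype=object)
    archetype[perm[:n_inc]] = "incomplete"
    archetype[perm[n_inc:n_inc + n_swp]] = "inconsistent"
    archetype[perm[n_inc + n_swp:n_inc + n_swp + n_out]] = "outlier"
    intercepts = rng.normal(0.0, cfg.intercept_sd, size=cfg.n_respondents)

    profiles = pd.DataFrame({
        "respondent_id": ids,
        "archetype": archetype,
        "random_intercept": intercepts,
    })

    # a non-positive grid step disables snapping for that method
    grids = {METHOD_VAS: cfg.vas_grid, METHOD_TTO: cfg.tto_grid / 10.0}
    rows: list[tuple[str, str, str, float, str]] = []
    for i, rid in enumerate(ids):
        arch = archetype[i]
        coefs = truth
        if arch == "inconsistent":
            dim = int(rng.integers(0, 5))
            coefs = {m: _swap_dimension(c, dim) for m, c in truth.items()}
        drop: dict[str, set[str]] = {m: set() for m in METHODS}
        if arch == "incomplete":
            m = METHODS[int(rng.integers(0, 2))]
            k = int(rng.integers(1, 4))
            drop[m] = set(rng.choice(non_anchor, size=k, replace=False))
        shift_cells: set[tuple[str, str]] = set()
        if arch == "outlier":
            cells = [(m, s) for m in METHODS for s in non_anchor]
            picked = rng.choice(len(cells), size=3, replace=False)
            shift_cells = {cells[j] for j in picked}

        for method in METHODS:
            c = coefs[method]
            noise = rng.normal(0.0, cfg.noise_sd, size=len(non_anchor))
            for j, lab in enumerate(non_anchor):
                if lab in drop[method]:
                    continue
                u = predict_state(c, design.states[j + 1]) + intercepts[i] + noise[j]
                u = _snap(u, grids[method])
                if (method, lab) in shift_cells:
                    shift = 4.0 * cfg.noise_sd + 0.5
                    u = u - shift if u >= 0 else u + shift
                    u = _snap(u, grids[method])
                rows.append(_raw_row(rid, method, lab, u))
            # anchor pinned at full health, no noise
            rows.append(_raw_row(rid, method, "11111", 1.0))

    responses = pd.DataFrame(rows, columns=["respondent_id", "method", "state",
                                            "raw", "direction"])
    responses = responses.sort_values(
        ["respondent_id", "method", "state"], kind="mergesort"
    ).reset_index(drop=True)
    return responses, profiles


def _snap(u: float, grid: float) -> float:
    if grid > 0.0:
        return snap_to_grid(u, grid)
    return float(min(1.0, max(-1.0, u)))


def _raw_row(rid: str, method: str, label: str, u: float):
    if method == METHOD_VAS:
        return (rid, method, label, 10.0 * u, "")
    direction = BTD if u >= 0 else WTD
    return (rid, method, label, 10.0 * abs(u), direction)
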