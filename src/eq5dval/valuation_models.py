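"""Value-set regression: dummy/N3 encoding, the four model specifications,
fitting, and tariff prediction.

The regression is Dolan-style: the dependent variable is disutility
(1 - utility) and the design matrix is *through the origin* so that full
health (11111) is predicted exactly 1. The possible terms are

* ten level dummies MO2..AD3 (1 if the dimension is at that level),
* N3 (1 if any dimension is at level 3),
* a "constant" implemented as the ANY indicator (1 for any state away from
  full health) — a fixed utility loss for leaving 11111, not a free intercept.

Coefficients are stored in the printed sign convention of published tariffs:
negative values are utility losses (the disutility regression is negated on
the way in and out), so fixture tables can be consumed verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elicitation import to_disutility
from .health_states import HealthState, enumerate_all_states, parse_state

__all__ = [
    "DUMMY_TERMS",
    "ModelSpec",
    "TermVector",
    "ValueSetCoefficients",
    "FitDiagnostics",
    "dummy_encode",
    "design_matrix",
    "fit_value_set",
    "predict_state",
    "predict_all",
    "PUBLISHED_SPECS",
]

#: The ten level dummies in canonical order (dimension order, level 2 then 3).
DUMMY_TERMS = ("MO2", "MO3", "SC2", "SC3", "UA2", "UA3", "PD2", "PD3", "AD2", "AD3")

CONSTANT_TERM = "constant"
N3_TERM = "N3"

ESTIMATORS = ("pooled-ols", "random-intercept-gls", "means-ols")


@dataclass(frozen=True)
class ModelSpec:
    """Which regression terms are active and how the model is estimated.

    The four published specifications are (constant+N3, VAS), (constant+N3,
    TTO), (neither, VAS) and (neither, TTO); constant and N3 always travel
    together there, but the flags are independent here.
    """

    include_constant: bool = False
    include_n3: bool = False
    estimator: str = "pooled-ols"

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(
                f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        """Active term names in design-matrix column order."""
        out: list[str] = []
        if self.include_constant:
            out.append(CONSTANT_TERM)
        out.extend(DUMMY_TERMS)
        if self.include_n3:
            out.append(N3_TERM)
        return tuple(out)


#: The four published model specifications keyed by their usual names.
PUBLISHED_SPECS: dict[str, tuple[ModelSpec, str]] = {
    "model1": (ModelSpec(True, True), "VAS"),
    "model2": (ModelSpec(True, True), "TTO"),
    "model3": (ModelSpec(False, False), "VAS"),
    "model4": (ModelSpec(False, False), "TTO"),
}


@dataclass(frozen=True)
class TermVector:
    """All 12 indicators for one state (masking to a spec happens later)."""

    MO2: int
    MO3: int
    SC2: int
    SC3: int
    UA2: int
    UA3: int
    PD2: int
    PD3: int
    AD2: int
    AD3: int
    N3: int
    ANY: int

    def values(self, terms: Sequence[str]) -> tuple[int, ...]:
        mapping = {CONSTANT_TERM: self.ANY}
        return tuple(mapping.get(t, getattr(self, t, None)) for t in terms)


def dummy_encode(state: HealthState) -> TermVector:
    """Indicator encoding of a state: level dummies, N3, and ANY."""
    ind: list[int] = []
    for lev in state.levels:
        ind.append(1 if lev == 2 else 0)
        ind.append(1 if lev == 3 else 0)
    n3 = 1 if 3 in state.levels else 0
    any_ind = 1 if state.levels != (1, 1, 1, 1, 1) else 0
    return TermVector(*ind, N3=n3, ANY=any_ind)


def design_matrix(states: Sequence[HealthState], spec: ModelSpec) -> pd.DataFrame:
    """Through-origin design matrix (rows = states, columns = active terms)."""
    rows = [dummy_encode(s).values(spec.terms) for s in states]
    return pd.DataFrame(rows, columns=list(spec.terms),
                        index=[s.label for s in states], dtype=float)


@dataclass(frozen=True)
class ValueSetCoefficients:
    """Fitted (or transcribed) decrements defining a tariff over all 243 states.

    ``coefficients`` maps active term names to values in the printed sign
    convention: dummy and constant terms are utility losses (negative); N3 may
    take either sign.
    """

    coefficients: Mapping[str, float]
    method: str = ""
    spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        missing = set(self.spec.terms) - set(self.coefficients)
        extra = set(self.coefficients) - set(self.spec.terms)
        if missing or extra:
            raise ValueError(
                f"coefficients must cover exactly the active terms; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )

    def dummy_values(self) -> dict[str, float]:
        return {t: float(self.coefficients[t]) for t in DUMMY_TERMS}


@dataclass
class FitDiagnostics:
    """Model-fit statistics computed at the level the model was fitted.

    adj_r2 uses the centred total sum of squares; aic/bic come from the
    Gaussian log-likelihood with k fitted coefficients (plus the two variance
    components for the random-intercept estimator's likelihood is *not*
    attempted — the FGLS point fit is summarised like the OLS fits).
    """

    n_obs: int
    k_params: int
    sigma2: float
    adj_r2: float
    aic: float
    bic: float
    theta: float = 0.0  # quasi-demeaning weight (random-intercept GLS only)


def _gaussian_ic(resid: np.ndarray, k: int) -> tuple[float, float, float]:
    n = resid.size
    sigma2 = float(resid @ resid) / n
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    aic = -2.0 * llf + 2.0 * k
    bic = -2.0 * llf + k * np.log(n)
    return sigma2, aic, bic


def _diagnostics(y: np.ndarray, resid: np.ndarray, k: int, theta: float = 0.0) -> FitDiagnostics:
    n = y.size
    sigma2, aic, bic = _gaussian_ic(resid, k)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k and tss > 0 else np.nan
    return FitDiagnostics(n_obs=n, k_params=k, sigma2=sigma2,
                          adj_r2=adj, aic=aic, bic=bic, theta=theta)


def _as_fit_frame(data, method: str | None) -> pd.DataFrame:
    """Normalise input to columns (respondent_id, state, disutility)."""
    if isinstance(data, pd.Series):
        df = data.rename("utility").rename_axis("state").reset_index()
        df["respondent_id"] = "__mean__"
    else:
        df = pd.DataFrame(data).copy()
        if method is not None and "method" in df.columns:
            df = df[df["method"] == method]
        if "respondent_id" not in df.columns:
            df["respondent_id"] = "__mean__"
    if "utility" not in df.columns:
        if {"raw", "method"} <= set(df.columns):
            from .elicitation import add_utilities

            df = add_utilities(df)
        else:
            raise ValueError(
                "fit input must carry a 'utility' column, a raw response schema, "
                "or be a Series of state means"
            )
    df["disutility"] = to_disutility(df["utility"].to_numpy())
    return df[["respondent_id", "state", "disutility"]]


def _check_identifiable(X: np.ndarray, spec: ModelSpec) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient for spec "
            f"{spec}; are all design states represented?"
        )


def _swamy_arora_theta(df: pd.DataFrame, X: np.ndarray, y: np.ndarray,
                       groups: np.ndarray) -> float:
    """Quasi-demeaning weight for the random-intercept feasible GLS.

    Variance components in the Swamy–Arora spirit on (near-)balanced data:
    the within-respondent residual variance comes from the fixed-effects
    (fully demeaned) regression; the between-respondent variance of
    respondent means minus its sampling share estimates the intercept
    variance tau^2; theta = 1 - sqrt(sigma_e^2 / (sigma_e^2 + T tau^2)).
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    counts = np.bincount(inv).astype(float)
    # within (fixed-effects) regression
    gy = np.bincount(inv, weights=y) / counts
    yw = y - gy[inv]
    Xw = X - np.vstack([np.bincount(inv, weights=X[:, j]) / counts
                        for j in range(X.shape[1])]).T[inv]
    bw, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ bw
    k = np.linalg.matrix_rank(Xw)
    dof = max(y.size - n_groups - k, 1)
    sigma_e2 = float(rw @ rw) / dof
    # between variance of respondent means
    T = float(counts.mean())
    var_between = float(np.var(gy, ddof=1)) if n_groups > 1 else 0.0
    tau2 = max(0.0, var_between - sigma_e2 / T)
    if tau2 == 0.0:
        return 0.0
    return 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + T * tau2))


def fit_value_set(data, spec: ModelSpec, method: str | None = None):
    """Fit a value-set specification; returns (coefficients, diagnostics).

    ``data`` is either a respondent-level table with columns
    (respondent_id, state, utility[, method]) or a Series of 18 state mean
    utilities indexed by label (then the means-OLS path is used regardless of
    ``spec.estimator``). The dependent variable is disutility and the design
    is through the origin, so the 11111 anchor contributes zero residual.
    """
    df = _as_fit_frame(data, method)
    states = [parse_state(s) for s in df["state"]]
    X = design_matrix(states, spec).to_numpy()
    y = df["disutility"].to_numpy()
    _check_identifiable(np.unique(X, axis=0), spec)

    estimator = spec.estimator
    if df["respondent_id"].nunique() == 1:
        estimator = "means-ols"

    theta = 0.0
    if estimator in ("pooled-ols", "means-ols"):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:  # random-intercept feasible GLS (quasi-demeaned OLS)
        groups = df["respondent_id"].to_numpy()
        theta = _swamy_arora_theta(df, X, y, groups)
        uniq, inv = np.unique(groups, return_inverse=True)
        counts = np.bincount(inv).astype(float)
        gy = np.bincount(inv, weights=y) / counts
        gX = np.vstack([np.bincount(inv, weights=X[:, j]) / counts
                        for j in range(X.shape[1])]).T
        yt = y - theta * gy[inv]
        Xt = X - theta * gX[inv]
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = y - X @ beta  # diagnostics on the original scale

    coefs = {t: -float(b) for t, b in zip(spec.terms, beta)}
    diag = _diagnostics(y, resid, k=len(spec.terms), theta=theta)
    vsc = ValueSetCoefficients(coefficients=coefs, method=method or "", spec=spec)
    return vsc, diag


def predict_state(c: ValueSetCoefficients, state: HealthState) -> float:
    """Predicted utility of one state: 1 plus the active (signed) decrements.

    Full health is predicted exactly 1 — the constant applies only to states
    away from 11111 (it enters as the ANY indicator).
    """
    tv = dummy_encode(state)
    vals = tv.values(c.spec.terms)
    return 1.0 + float(sum(c.coefficients[t] * v for t, v in zip(c.spec.terms, vals)))


def predict_all(c: ValueSetCoefficients) -> pd.Series:
    """The full tariff: predicted utilities for all 243 states by label."""
    states = enumerate_all_states()
    return pd.Series({s.label: predict_state(c, s) for s in states}, name="utility")
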