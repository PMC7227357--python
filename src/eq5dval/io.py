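"""File formats, packaged fixtures, pipeline configuration and orchestration.

Everything the pipeline reads or writes is plain CSV/JSON. The three packaged
fixtures (transcribed observed tables) are:

* ``design_states`` — the 18-state valuation design (index, label);
* ``table3_summary`` — per-state observed summary (mean, SD, quartiles) for
  both methods plus a separate "total" row per method;
* ``table4_coefficients`` — the four published coefficient columns
  (models 1/2 with constant + N3, models 3/4 with the 10 dummies only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptives import btd_wtd_shares, grand_summary, summarize_states
from .elicitation import BTD, METHOD_TTO, METHOD_VAS, METHODS, RESPONSE_COLUMNS, WTD
from .evaluation import compare_value_sets, export_curve_data, logical_error_count, prediction_errors
from .health_states import parse_state
from .quality_control import QCConfig, apply_exclusions
from .synthetic_cohort import CohortConfig, generate_cohort
from .valuation_models import (
    PUBLISHED_SPECS,
    ModelSpec,
    ValueSetCoefficients,
    fit_value_set,
    predict_all,
)

__all__ = [
    "read_responses",
    "write_responses",
    "load_fixture",
    "value_set_to_json",
    "value_set_from_json",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("eq5dval")

FIXTURES = ("design_states", "table3_summary", "table4_coefficients")


class ResponseSchemaError(ValueError):
    """A response CSV row violates the schema."""


def read_responses(path) -> pd.DataFrame:
    """Read and validate a response CSV (respondent_id, method, state, raw,
    direction). TTO rows must carry a BTD/WTD direction; VAS rows must not."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "state": str},
                     keep_default_na=False)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ResponseSchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        if row.method not in METHODS:
            raise ResponseSchemaError(f"{path}:{i}: unknown method {row.method!r}")
        try:
            parse_state(row.state)
        except ValueError as e:
            raise ResponseSchemaError(f"{path}:{i}: column 'state': {e}") from e
        try:
            raw = float(row.raw)
        except (TypeError, ValueError) as e:
            raise ResponseSchemaError(f"{path}:{i}: column 'raw': not a number") from e
        if row.method == METHOD_VAS:
            if not -10.0 <= raw <= 10.0:
                raise ResponseSchemaError(f"{path}:{i}: VAS mark {raw} outside [-10, 10]")
            if str(row.direction) not in ("", "nan"):
                raise ResponseSchemaError(f"{path}:{i}: VAS rows must not carry a direction")
        else:
            if not 0.0 <= raw <= 10.0:
                raise ResponseSchemaError(f"{path}:{i}: TTO years {raw} outside [0, 10]")
            if row.direction not in (BTD, WTD):
                raise ResponseSchemaError(
                    f"{path}:{i}: TTO rows need direction {BTD}/{WTD}, got {row.direction!r}")
    df["raw"] = df["raw"].astype(float)
    return df[list(RESPONSE_COLUMNS)]


def write_responses(df: pd.DataFrame, path) -> None:
    df[list(RESPONSE_COLUMNS)].to_csv(path, index=False)


def _fixture_path(name: str):
    return resources.files("eq5dval").joinpath("data", f"{name}.csv")


def load_fixture(name: str):
    """Load a packaged fixture by name.

    * ``design_states`` -> list of 18 HealthState in protocol order
    * ``table3_summary`` -> (per-state summary frame indexed by (state,
      method), totals frame indexed by method)
    * ``table4_coefficients`` -> dict model name -> ValueSetCoefficients
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p, dtype={"label": str, "state": str})
    if name == "design_states":
        return [parse_state(lab) for lab in df["label"]]
    if name == "table3_summary":
        totals = df[df["state"] == "total"].set_index("method")
        summary = df[df["state"] != "total"].set_index(["state", "method"])
        return summary, totals
    # table4_coefficients
    out: dict[str, ValueSetCoefficients] = {}
    table = df.set_index("term")
    for model, (spec, method) in PUBLISHED_SPECS.items():
        col = table[model].dropna()
        coefs = {t: float(col[t]) for t in spec.terms}
        out[model] = ValueSetCoefficients(coefficients=coefs, method=method, spec=spec)
    return out


def value_set_to_json(c: ValueSetCoefficients, include_tariff: bool = False) -> dict:
    doc = {
        "method": c.method,
        "spec": {
            "constant": c.spec.include_constant,
            "n3": c.spec.include_n3,
            "estimator": c.spec.estimator,
        },
        "coefficients": {t: float(v) for t, v in c.coefficients.items()},
    }
    if include_tariff:
        doc["tariff"] = {k: float(v) for k, v in predict_all(c).items()}
    return doc


def value_set_from_json(doc: dict) -> ValueSetCoefficients:
    spec = ModelSpec(
        include_constant=bool(doc["spec"]["constant"]),
        include_n3=bool(doc["spec"]["n3"]),
        estimator=doc["spec"].get("estimator", "pooled-ols"),
    )
    return ValueSetCoefficients(coefficients=dict(doc["coefficients"]),
                                method=doc.get("method", ""), spec=spec)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Full-run configuration: cohort generation, QC, and the model list."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    models: tuple[str, ...] = ("model1", "model2", "model3", "model4")
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        cohort = CohortConfig(**doc.get("cohort", {}))
        qc_doc = dict(doc.get("qc", {}))
        if "percentile_bounds" in qc_doc:
            qc_doc["percentile_bounds"] = tuple(qc_doc["percentile_bounds"])
        qc = QCConfig(**qc_doc)
        return cls(cohort=cohort, qc=qc,
                   models=tuple(doc.get("models", cls().models)),
                   log_level=doc.get("log_level", "INFO"))


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """simulate -> qc -> describe -> fit -> predict -> evaluate -> compare.

    Writes all artifacts under ``outdir`` and returns the run manifest (also
    written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    logger.info("simulate: %d respondents, seed %d", cfg.cohort.n_respondents,
                cfg.cohort.seed)
    responses, profiles = generate_cohort(cfg.cohort)
    write_responses(responses, out / "responses.csv")
    profiles.to_csv(out / "profiles.csv", index=False)

    clean, report = apply_exclusions(responses, cfg.qc)
    report.to_csv(out / "qc_report.csv", index=False)
    retained = int((~report["excluded"]).sum())
    logger.info("qc: %d/%d respondents retained", retained, len(report))

    summaries = {}
    for m in METHODS:
        s = summarize_states(clean, m)
        summaries[m] = s
        s.to_csv(out / f"state_summary_{m.lower()}.csv")

    diagnostics_rows = []
    fitted: dict[str, ValueSetCoefficients] = {}
    tariffs: dict[str, pd.Series] = {}
    for model in cfg.models:
        spec, method = PUBLISHED_SPECS[model]
        coefs, fit_diag = fit_value_set(clean, spec, method=method)
        fitted[model] = coefs
        with open(out / f"value_set_{model}.json", "w") as fh:
            json.dump(value_set_to_json(coefs, include_tariff=True), fh, indent=1)
        tariff = predict_all(coefs)
        tariffs[model] = tariff
        errs = prediction_errors(coefs, summaries[method]["mean"])
        diagnostics_rows.append({
            "model": model, "method": method,
            "mae": errs.mae, "n_gt_005": errs.n_err_gt_005,
            "n_gt_010": errs.n_err_gt_010, "r": errs.r,
            "logical_errors": logical_error_count(tariff),
            "adj_r2": fit_diag.adj_r2, "aic": fit_diag.aic, "bic": fit_diag.bic,
        })
    diagnostics = pd.DataFrame(diagnostics_rows)
    diagnostics.to_csv(out / "diagnostics.csv", index=False)

    comparisons = []
    pairs = [(a, b) for i, a in enumerate(cfg.models) for b in cfg.models[i + 1:]]
    for a, b in pairs:
        if fitted[a].spec.terms != fitted[b].spec.terms:
            continue
        rep = compare_value_sets(fitted[a], fitted[b])
        comparisons.append({
            "model_a": a, "model_b": b,
            "max_abs_dummy_diff": rep.max_abs_dummy_diff,
            "max_term": rep.max_term,
            "tariff_correlation": rep.tariff_correlation,
        })
    pd.DataFrame(comparisons).to_csv(out / "comparison.csv", index=False)
    export_curve_data(tariffs).to_csv(out / "curves.csv")

    btd_vas = btd_wtd_shares(clean, METHOD_VAS)[0]
    btd_tto = btd_wtd_shares(clean, METHOD_TTO)[0]
    gm = {m: grand_summary(summaries[m]) for m in METHODS}
    manifest = {
        "version": __version__,
        "seed": cfg.cohort.seed,
        "config": {
            "cohort": _jsonable(asdict(cfg.cohort)),
            "qc": asdict(cfg.qc),
            "models": list(cfg.models),
        },
        "counts": {
            "respondents_in": cfg.cohort.n_respondents,
            "respondents_retained": retained,
            "respondents_excluded": int(report["excluded"].sum()),
            "exclusions_by_reason": _reason_counts(report),
            "responses_in": int(len(responses)),
            "responses_retained": int(len(clean)),
        },
        "grand_mean": {m: gm[m][0] for m in METHODS},
        "grand_sd": {m: gm[m][1] for m in METHODS},
        "btd_share": {"VAS": btd_vas, "TTO": btd_tto},
        "diagnostics": diagnostics.to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _reason_counts(report: pd.DataFrame) -> dict[str, int]:
    counts = {"incomplete": 0, "inconsistent": 0, "outlier": 0}
    for reasons in report.loc[report["excluded"], "reasons"]:
        for r in str(reasons).split(";"):
            if r:
                counts[r] += 1
    return counts


def _jsonable(doc):
    if isinstance(doc, dict):
        return {k: _jsonable(v) for k, v in doc.items()}
    if isinstance(doc, (list, tuple)):
        return [_jsonable(v) for v in doc]
    if isinstance(doc, (np.floating, np.integer)):
        return doc.item()
    return doc
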