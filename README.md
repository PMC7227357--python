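# eq5dval

A tested Python pipeline for **EQ-5D-3L valuation studies**: transforming raw
visual-analogue-scale (VAS) and time-trade-off (TTO) elicitations onto the
anchored −1 ~ 0 ~ 1 utility scale, screening respondents, fitting Dolan-style
value-set regressions, and comparing the resulting 243-state tariffs across
elicitation methods.

It is aimed at health economists and outcomes researchers who construct or
audit EQ-5D value sets. Because respondent-level valuation data is rarely
shared, the package includes a synthetic-cohort generator with the statistical
structure such studies assume (balanced 18-state design, respondent random
intercepts, gridded responses, controlled rates of incomplete, logically
inconsistent and outlying respondents), so every stage runs and is testable
end to end without any external data.

## The model

An EQ-5D-3L health state scores five dimensions — mobility (MO), self-care
(SC), usual activities (UA), pain/discomfort (PD), anxiety/depression (AD) —
at three levels, giving 3⁵ = 243 states labelled like `31122`. A valuation
study elicits utilities for a balanced subset (here 18 states from an
L18(2×3⁷) orthogonal array, anchored by full health `11111` ≡ 1 and dead ≡ 0)
and generalises with an additive regression on disutility (1 − utility),
through the origin:

```
1 − u(s) = C·ANY(s) + Σ_d [ β_d2·I(level_d = 2) + β_d3·I(level_d = 3) ] + β_N3·N3(s)
```

where `ANY` indicates any departure from full health (the "constant", a fixed
loss rather than a free intercept), the ten level dummies MO2…AD3 carry the
per-dimension decrements, and `N3` indicates any level-3 problem. Four
specifications are supported: VAS and TTO, each with or without the
constant + N3 terms. Estimators: pooled OLS (default), OLS on state means,
and a random-intercept feasible GLS (quasi-demeaning, Swamy–Arora-type
variance components). Diagnostics include the mean absolute error against
observed state means (over the 17 non-anchor states), strict error counts
(> 0.05, > 0.1), Pearson r (18 states), and an exhaustive dominance scan of
the 243-state tariff over all 7533 comparable ordered pairs ("logical
errors").

## Worked example

Evaluate the packaged VAS 10-dummy coefficient column against the packaged
observed state means, then compare the two constant + N3 models:

```bash
$ eq5dval evaluate --value-set model3.json --method VAS
{"mae": 0.0327, "n_gt_005": 4, "n_gt_010": 0, "r": 0.9813, "logical_errors": 0}

$ eq5dval compare --value-set-a model1.json --value-set-b model2.json
{"max_abs_dummy_diff": 0.0586, "max_abs_dummy_diff_3dp": 0.059, "max_term": "PD3", "tariff_correlation": 0.9789}
```

Reading: the VAS tariff predicts the 17 non-anchor observed means with a mean
absolute error of 0.0327 utility points (4 states miss by more than 0.05,
none by more than 0.1), correlates with them at r = 0.9813, and contains no
dominance violation among all 243 predicted states. The largest disagreement
between the VAS and TTO dummy coefficients is 0.059 (PD3) — the two methods
produce nearly interchangeable value sets under this protocol.

The full pipeline (simulate → screen → summarise → fit → predict → evaluate →
compare) runs from one seed:

```bash
$ eq5dval run --seed 1 --out out/
{"respondents_in": 313, "respondents_retained": 313, "respondents_excluded": 0, "exclusions_by_reason": {"incomplete": 0, "inconsistent": 0, "outlier": 0}, "responses_in": 11268, "responses_retained": 11268}
```

and leaves `responses.csv`, `qc_report.csv`, per-method state summaries,
four value-set JSONs, `diagnostics.csv`, `comparison.csv`, `curves.csv` and a
`manifest.json` in `out/`. The same library surface is importable
(`from eq5dval import fit_value_set, predict_all, ...`).

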