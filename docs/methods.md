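# Methods

This note documents the statistical model, the conventions that make the
numbers reproducible, the synthetic-cohort generator, and the design choices
taken where more than one reasonable convention exists.

## Scales and transforms

Both elicitation methods live on a common utility scale anchored at dead = 0
and full health = 1, bounded below at −1 (worst imaginable state):

* **VAS**: a mark x on a −10..10 thermometer; utility u = x/10.
* **TTO** over a 10-year horizon: a better-than-death state matched to t
  years of full health gives u = t/10; a worse-than-death state where t years
  of full health compensate (10 − t) years in the state gives u = −t/10.
  An alternative worse-than-death rescaling of the form −t/(10 − t) exists in
  older protocols; it is deliberately not implemented — the bounded −t/10
  form is the one this pipeline models throughout.
* **Disutility** 1 − u is the regression dependent variable.

Responses are gridded: VAS marks default to integers (utility step 0.1),
TTO trades to 0.1 years. Snapping rounds to the nearest grid multiple with
ties away from zero (symmetric about the dead anchor) and clamps to [−1, 1].

## The valuation design

The 18 valued states come from an L18(2×3⁷) orthogonal array restricted to
the five EQ-5D dimensions: every level of every dimension appears exactly 6
times, and both `11111` and `33333` are included. The anchor `11111` is kept
in the estimation sample with utility exactly 1. One historical rendering of
the design prints state 3 as `21113`; the packaged fixture uses `22113`,
which is the label that (a) preserves the exact 6/6/6 column balance an L18
array requires and (b) is consistent with the published per-state summaries.
A `legacy_table1` toggle swaps the variant in for sensitivity checks.

Sample size uses the precision formula n = ⌈z²₁₋α/₂ σ²/δ²⌉; the ceiling is
taken because a count rounded down would miss the precision target
(α = 0.05, δ = 0.05, σ = 0.4 gives 246).

## Regression model

The design matrix is **through the origin** on disutility. Terms: ten level
dummies (MO2…AD3), optionally N3 (any level-3 problem) and a "constant"
implemented as the ANY indicator (1 for every state except `11111`). This
Dolan-style constant is a fixed loss for leaving full health, not a free
intercept: full health is predicted exactly 1 and contributes zero residual,
which is also what makes the anchor's prediction error identically 0.
Coefficients are stored in the published sign convention (negative = utility
loss), so transcribed tariff tables can be consumed verbatim; the regression
layer negates internally.

Estimators:

* **pooled OLS** (default): on a balanced design (every respondent values
  all 18 states) its coefficients coincide with OLS on the 18 state means to
  machine precision, which is the package's reproducibility argument.
* **means OLS**: the same fit computed from per-state mean utilities.
* **random-intercept GLS**: feasible GLS with quasi-demeaning. Variance
  components are estimated Swamy–Arora-style — the within-respondent
  residual variance from the fully demeaned (fixed-effects) regression, the
  intercept variance from the between-respondent variance of respondent
  means minus its sampling share — giving θ = 1 − √(σ²ₑ/(σ²ₑ + Tτ²)); the
  fit is OLS on (y − θȳᵢ) against (X − θx̄). When τ̂² = 0 the estimator
  collapses exactly to pooled OLS. It is cross-checked in the test suite
  against statsmodels MixedLM (REML), which agrees on fixed effects to
  ~1e-6 on simulated cohorts.

**A caveat that matters for reproduction.** The textbook result "random
effects = OLS on balanced panels" holds for models *with* a free intercept.
In a through-origin specification nothing absorbs the quasi-demeaning shift,
so GLS and OLS coefficients differ whenever τ̂² > 0 — on realistic cohorts by
a few 1e-4, i.e. within 4-decimal reporting precision but far from machine
equality. Consequently, a published coefficient column estimated by
respondent-level GLS is generally *not* exactly recoverable from the state
means alone: the means-OLS refit of the packaged observed summary deviates
from the packaged coefficient columns by up to ~0.007 on individual dummies,
while a quasi-demeaned refit with θ ≈ 0.69 reproduces the TTO column to
3e-4 (θ requires respondent-level variance components that state means do
not contain). The package therefore treats transcribed coefficient columns
as inputs for diagnostics, and treats means-based refits as approximations.

Adjusted R², AIC and BIC are computed from the Gaussian log-likelihood of
the residuals at the level the model was fitted (R² uses the centred total
sum of squares). They are reported for completeness on synthetic data only;
their published counterparts depend on respondent-level data and are not
comparison targets.

## Diagnostics

* **MAE** averages |observed mean − predicted| over the **17 non-anchor**
  states. The anchor is predicted exactly 1 by construction, and only with
  the 17-state denominator do the packaged coefficient columns reproduce the
  published MAE values (0.0304 / 0.0269 / 0.0327 / 0.0310) at 4 decimals.
* The > 0.05 and > 0.1 **error counts** are strict inequalities over the same
  17 states (the largest sub-threshold TTO error is 0.0499, so inclusive
  thresholds would change the counts).
* **Pearson r** uses all 18 states; this convention reproduces the published
  0.9847 / 0.9879 / 0.9813 / 0.9867 exactly at 4 decimals, so no 17-state
  fallback is needed.
* **Logical errors**: over the 243-state tariff, every ordered pair (a, b)
  with a dominating b (element-wise ≤ with at least one strict) is scanned —
  6⁵ − 243 = 7533 comparable pairs — and counted when the tariff ranks a
  strictly below b. Exact ties are not errors. The vectorised scan is tested
  against a naive double loop.
* **Cross-model comparison** reports signed per-term differences and the
  maximum absolute difference over the 10 dummies only (constant and N3
  excluded), raw and at 3 decimals, plus per-state tariff differences.

## Quality control

* **Inconsistencies**: each respondent × method's 18 utilities are fit with
  the 10-dummy through-origin model (11 would be the parameter count with a
  constant; 10 dummies on 18 observations is the richest specification that
  is always identifiable on this design and mirrors the no-constant models).
  Each dimension must satisfy b2 ≥ 0, b3 ≥ b2, b3 ≥ 0 in disutility space —
  15 orderings in all. Strict reversals count; exact ties are consistent,
  because coarse grids make ties common. Exclusion when more than 4 fail in
  either method.
* **Outliers**: within each state's cross-respondent distribution (per
  method), a value is flagged only if it is strictly beyond the 1.5·IQR
  Tukey fence, strictly more than 3·IQR from the nearest quartile, and
  strictly outside P5/P95. Quartiles use linear interpolation (shared with
  the descriptives module). Flags are summed over both methods; exclusion
  when more than 2. Detection requires at least 20 respondents per state.
* **Completeness**: any missing design state in either method excludes the
  respondent from both.
* The **SD flag** (|SD of the 18 raw-scale values − 2.5| < 0.5) was an
  interactive plausibility signal during data collection; it is reported in
  the QC table but never excludes anyone.

## Synthetic cohorts

The generator emulates the study conditions: 313 respondents × 18 states × 2
methods (11,268 responses), utility = tariff prediction + respondent random
intercept + noise, snapped to the response grid, anchor pinned at 1. The
default truth is the packaged 10-dummy VAS and TTO coefficient columns; the
default variance components are τ = 0.10 (between respondents) and
σₑ = 0.15 (within), chosen once so that simulated per-state SDs land in the
0.13–0.25 range of the observed summaries — no respondent-level variance
estimates are published, so these are conventions, not estimates.

Contamination is assigned **by quota** from a seeded permutation (realised
counts equal the configured fractions exactly, making QC tests exact):
incomplete respondents drop 1–3 non-anchor states from one method;
inconsistent respondents have one dimension's level-2/3 decrements swapped
before sampling; outlier respondents have 3 values shifted toward the
opposite sign by 4σₑ + 0.5. All randomness comes from one root seed, drawn
in a fixed order, so equal seeds give byte-identical tables.

What the generator does **not** emulate: interviewer effects, within-task
learning or the interactive re-valuation loop, respondent × dimension
interactions, and the empirical BTD/WTD percentages of any particular
population. Passing recovery and QC tests on these cohorts therefore shows
the pipeline is correct under its stated assumptions, not that the
assumptions hold for any real population.

Default QC test conditions: the contaminated-cohort checks use n = 60 with
τ = σₑ = 0.05 so that clean respondents' per-respondent fits stay far from
the inconsistency and outlier thresholds and the cascade's behaviour on the
injected archetypes is unambiguous; recovery checks use the full n = 313
with the default variance components over three seeds (±0.02 on every
decrement). Problem sizes throughout the tests (25–313 respondents) keep the
whole suite in the seconds range.

## Numerical conventions and degenerate inputs

* Lexicographic label order is the canonical ordering everywhere.
* Sample SDs use the n − 1 denominator; percentiles linear interpolation.
* Zero as a utility counts as better-than-death (the dead point is reached
  from the BTD elicitation branch).
* A non-positive grid step disables snapping (used by noise-free tests).
* Rank-deficient design matrices (missing states) raise rather than fit.
* Balanced-input checks guard the summary-based grand mean: with unequal
  per-state n the unweighted mean of state means is not the overall mean,
  and the function refuses rather than silently reweight.

## Known limitations

* Published goodness-of-fit statistics that require respondent-level raw
  data (adjusted R², AIC/BIC, per-state SDs, BTD/WTD shares) are computed
  but cannot be compared against their published values; they are covered by
  property tests on synthetic data instead.
* The means-OLS refit of transcribed state means approximates, but does not
  exactly reproduce, coefficient columns estimated by respondent-level GLS
  (see the through-origin caveat above).
* The elicitation state machine (iterative 1-year decrements, then decimal
  refinement) is not simulated step by step; only the final indifference
  point enters any computation, so the generator produces it directly.
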