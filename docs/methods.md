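# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `lifelost`, at the level of detail a maintainer or
a careful user needs.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model

### Excess hazard on the log cumulative scale

For each cancer type and sex the all-cause hazard of a patient with
covariates `x` at time `t` since diagnosis is decomposed as
`h(t|x) = h*(t) + λ_E(t|x)`: an expected (background) part taken from a
population life table matched on sex, deprivation quintile, attained age
and attained calendar year, plus an excess part attributed to the cancer.
The excess part is modelled on the log cumulative scale,

    η(t|x) = ln Λ_E(t|x)
           = s(ln t; γ) + dep'β_dep + a(age)'β_age + (a(age) ⊗ dep)'β_int
             + Σ_l s_l(ln t; δ_l) x_l ,

where `s` and `s_l` are restricted cubic splines in `ln t`, `a(age)` is a
restricted cubic spline in age at diagnosis, `dep` holds quintile dummies
(levels 2–5 against the least deprived), and the `s_l` blocks give
time-dependent (non-proportional) effects to the deprivation dummies and
the age-spline columns.  Each time-dependent block uses the full spline
basis of `ln t` (its linear term included; the proportional main effect is
a separate column, so there is no collinearity).  The excess hazard and
relative survival follow as

    λ_E = Λ_E · (∂η/∂ ln t) / t ,    R(t|x) = exp(−Λ_E(t|x)) .

Restricted cubic splines are linear beyond their boundary knots, so `η` is
linear in `ln t` beyond the last knot: extrapolated relative survival has a
Weibull-like tail whose exponent (`tail_slope` in the results object) is
reported per covariate pattern.  This linear-tail behaviour is the entire
justification for extrapolating `R` rather than all-cause survival: at
long times the background hazard dominates the all-cause mortality of
survivors, so modest misspecification of the `R` tail has bounded effect
on life expectancy.

### Period analysis likelihood

The analysis dataset keeps everyone under follow-up at any point in a
calendar window `[w_start, w_end)` (default 2007.0–2014.0, i.e. through
31 December 2013).  Entry is delayed to the window start for earlier
diagnoses (`t0 = max(0, w_start − date_dx)`), follow-up is censored at the
window end, and each subject contributes

    ℓ_i = d_i ln( h*_i(t_i) + λ_E(t_i|x_i) ) − Λ_E(t_i|x_i) + Λ_E(t0_i|x_i) ,

the parameter-free expected cumulative-hazard terms being dropped.  The
expected hazard at the event time is looked up at the subject's own
attained age and calendar year (never averaged over the cohort).

Flexible spline shapes can make `λ_E` transiently negative.  During
optimisation the log of the total hazard `u = h* + λ_E` is replaced by
`ln(ε·softplus(u/ε))` with `ε = 1e-10` — a C^∞ surrogate equal to `ln u`
for `u ≫ ε` and finite for `u ≤ 0` — and the number of event times with
`u ≤ ε` remaining at the optimum is reported (`n_guard_violations`);
violations are surfaced, never silently clipped.

### Estimation

Maximisation is quasi-Newton (BFGS with the analytic score; one L-BFGS-B
retry if the gradient tolerance is missed, then a hard error unless
`force=True`).  Initialisation is deterministic: a Weibull-equivalent
start (`η = ln λ̂₀ + ln t` at the crude excess rate, everything else zero)
for a proportional-effects model whose solution warm-starts the
time-dependent model.  Design columns are optionally standardised (mean 0,
sd 1; on by default) for optimizer conditioning; the transform is stored in
the model object so predictions are invariant to it, and a test asserts
this.  Standard errors come from the observed information, obtained by
central finite differences of the analytic score (the likelihood, score
and their agreement with numerical differentiation are unit-tested to
1e-5 relative).  No confidence intervals are produced for the
life-expectancy measures.

Default knot placement: baseline spline 5 df (6 knots) at quantiles of the
log event times with boundary knots at the extremes; time-dependent
splines 3 df; age spline 3 df with boundary knots at the 2nd/98th age
percentiles.  All are configurable (`FitConfig`), and `df_age=0`, `td=()`
or single-quintile data degrade gracefully to simpler models.  With two
knots a spline is exactly linear.

## Life tables and integration

Life tables are rectangular arrays of *annual hazards* over sexes ×
quintiles 1–5 × ages 0..age_cap (≥ 99) × a calendar-year range; ragged
input is rejected with the first missing key named.  Conventions, chosen
to match standard rate-table semantics:

- dates are decimal years (2007.0 = 1 January 2007); no calendar-day
  arithmetic — the inputs have annual resolution anyway;
- attained age is `floor(age_at_diagnosis + t)`, so a fractional age at
  diagnosis makes the first age segment a fraction of a year;
- attained ages above `age_cap` reuse the `age_cap` row; attained years
  outside the tabulated range reuse the nearest tabulated year.  Reusing
  the last year (a constant-future assumption) is the default
  extrapolation of background mortality; it is deliberately conservative
  and can be probed by supplying tables with other future assumptions.

Expected survival is therefore piecewise exponential with breakpoints at
every integer attained age and every 1 January, and both `E*` and the
within-segment survival factor of `E` are computed *exactly* segment by
segment (`S₀(1−e^{−rΔ})/r`, with the `r→0` limit).  The relative-survival
factor is smooth inside segments, so `E = ∫ S*·R` uses fixed-order
Gauss–Legendre quadrature (order 15 per segment by default) with nodes
that never straddle a segment boundary; the life-table step structure
contributes no quadrature error.  Doubling the order moves `E` by less
than 1e-4 years in the test scenarios (self-convergence test), and the
exact-segment `E*` matches closed forms to 1e-9 relative.

The default integration horizon is `τ = age_cap + 1 − age + 20` years
(attained age 120 for a standard table), where `S*` is numerically zero,
and the *same* `τ` is used for `E*` and `E` so `PLL = LEL/E*` is a true
ratio.  Predictions fix the diagnosis year at 2013.0 by default — the
reference cohort year — and both are configurable.

## Standardisation and totals

Age-specific results are combined with weights that sum to one:

- **internal** (default): each deprivation group's own reference-year
  (2013) diagnoses, by single year of age;
- **external pooled**: the reference-year age distribution pooled over
  groups;
- **external custom**: arbitrary `(lo, hi)` age bands with user-supplied
  weights read from CSV (e.g. the International Cancer Survival Standard;
  the weight values are input data, not constants of this package), with
  age-specific estimates evaluated at band midpoints.

The mean proportion of life lost is by default the weighted mean of the
age-specific ratios; the ratio of weighted means `Σw·LEL / Σw·E*` is
available as `pll_mode="ratio_of_means"` since the two readings are both
defensible and differ when `E*` varies strongly over the weighted ages.
An alternative `average="per-patient"` mode evaluates the loss at every
reference-year patient's exact age, which is internal standardisation at
full resolution.  Totals are `N_referenceyear × mean LEL`, computed from
unrounded means; presentation tables round to 2 dp only at render time, so
recomputing a total from *printed* rounded means can disagree with the
printed total by ~0.1% — expected, and covered by a test.

## Synthetic registries and ground truth

The generator emulates the structure the estimator assumes, with exact
truth available by construction:

- background mortality: Gompertz–Makeham per quintile,
  `h*(age) = c + α e^{β·age}`, with a secular improvement factor `ρ` per
  calendar year, tabulated into a life table exactly as published tables
  are; background death times are sampled from the *tabulated* table (the
  same object handed to estimation), so expected-mortality
  misspecification is zero by construction — robustness to a wrong table
  can be studied by passing a different table to the estimator;
- diagnoses: Poisson counts per calendar year (1998–2013) and quintile,
  with truncated-normal ages per quintile (means ≈ 70–72, echoing
  national registry case mix; bounds 30–94);
- excess hazard: Weibull `λ_E(t|x) = λ₀ k t^{k−1} e^{θ_dep + θ_age(age−70)}`
  with an optional cured fraction, giving proportional excess hazards whose
  log-linear age effect the age spline can represent exactly.

The default scenario (~100 000 patients; `default_scenario`) uses
`λ₀ = 0.19, k = 0.8` (5-year relative survival ≈ 0.5 at age 70 in the
least deprived), a ~30%-per-quintile background gradient, and excess log
hazard ratios `(0, 0.14, 0.28, 0.42, 1.06)` — a graded deterioration with
a sharply worse most-deprived group.  The gradients were chosen once, at
design time, so that each group's *true* standardised summary is separated
from its neighbours by clearly more than the Monte-Carlo error of the
internal weights and the fitted coefficients at this cohort size
(adjacent true gaps ≈ 0.25+ years LEL and 0.012+ PLL); with near-tied
truths an ordering comparison would test a coin flip rather than the
pipeline.  A `reversal_scenario` combines a strong background gradient
with a mild excess gradient to reproduce the proportional-scale trend
reversal: most absolute years lost in the least deprived, largest share of
life lost in the most deprived.  Note that this reversal *requires* an
excess-hazard gradient: with exactly equal relative survival across
groups, a higher background hazard reweights the non-increasing `R(t)`
toward early follow-up where it is largest, so the proportion of life lost
can only *fall* with deprivation (the exponential closed form
`PLL = λ/(μ+λ)` makes this explicit); that equal-`R` mechanism is covered
by its own test.

`compute_truth` integrates the scenario's closed-form hazards (with the
same floor/cap/clamp semantics the table lookups use) by plain trapezoid
on a 0.001-year grid — an independent code path from the piecewise-exact
estimator route — and agrees with it to ~1e-3 years.

What the generator does **not** emulate: late registration and loss to
follow-up, cause-of-death coding, within-quintile heterogeneity of
background mortality, stage at diagnosis, screening-induced lead time, and
secular trends in the excess hazard.  Passing tests therefore demonstrate
that the estimator chain is correct under its own assumptions at realistic
scale — not that those assumptions hold in any particular registry.

## Validation scenarios and problem sizes

The self-check fits (`lifelost.validation`, also driven by
`scripts/acceptance.py`) use a proportional-effects configuration
(baseline 4 df, age 2 df, no time-dependent terms, no interaction): the
simulation truth is proportional with a log-linear age effect, and the
parsimonious baseline keeps the extrapolated tail stable.  The
time-dependent and interaction machinery is exercised by its own unit and
smoke tests.  Problem sizes — 20 000 patients for the exponential oracle,
~100 000 for truth recovery, ~60 000 for the reversal — keep the whole
suite and the acceptance script in the tens of seconds on one CPU while
leaving Monte-Carlo error well inside the tolerances checked.

## Degenerate inputs and edge rules

- Same-day (zero-length) registry records get one day (1/365.25 y) of
  follow-up before window clipping; rows still empty after clipping are
  dropped with a logged count.  The window end is exclusive.
- Duplicate (id, cancer) records: the earliest diagnosis is kept,
  ties broken by input order (deterministic).
- Zero-exposure rows (`t0 = t`) contribute nothing to the likelihood and
  are tolerated by the model object.
- `t ≤ 0` in predictions, negative times, non-increasing knots, ragged or
  negative-rate life tables, weights not summing to a positive value, and
  mismatched weight/result strata all raise immediately with the offending
  key named.
- Fewer events than parameters is an error at `fit` time, as is
  non-convergence (unless `force=True`, which returns the diagnostics for
  inspection).

## Known limitations

- No variance or confidence intervals for LEL/PLL (the point estimates are
  the deliverable; the delta method over the spline coefficients would be
  the natural extension).
- Ederer I / Hakulinen expected-survival weighting variants, cure-fraction
  models and frailty terms are out of scope.
- Background-mortality extrapolation beyond the last tabulated year is
  constant; mortality-improvement projections must be supplied as input
  tables if wanted.
- The period window, like any period analysis, assumes recent survival
  conditions persist; no calendar-trend modelling inside the window.
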