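# lifelost

Loss in expectation of life after a cancer diagnosis, by socio-economic
group, from flexible parametric relative-survival models.

## The problem

Point-in-time metrics such as 5-year relative survival say little about the
*life-time* impact of a cancer diagnosis, and nothing about how that impact
is distributed across socio-economic groups.  Two complementary measures do:

- **Loss in expectation of life (LEL)** — the difference between the life
  expectancy of comparable people without the cancer and the life
  expectancy of the patients: `LEL = E* − E` with

      E* = ∫₀^τ S*(t) dt         E = ∫₀^τ S*(t) R(t|x) dt

  where `S*` is expected survival from a population life table matched on
  sex, age, calendar year and deprivation quintile, and `R(t|x)` is the
  patients' relative survival.
- **Proportion of life lost (PLL)** — `LEL / E*`, which is far less
  age-dependent and allows a "share of remaining life" reading.

Group summaries weight age-specific estimates by each group's own recent
age-at-diagnosis distribution (internal standardisation), and population
burden is `total years lost = N(reference year) × mean LEL`.

This package is for biostatisticians and cancer-epidemiology analysts who
want these quantities from person-level registry data plus a population
mortality file — or who want to study the estimators themselves on
synthetic registries with known truth.

## The model

The excess-hazard (relative-survival) model places a restricted cubic
spline of log time on the log cumulative excess hazard:

    ln Λ_E(t | x) = s(ln t; γ) + x'β + Σ_l s_l(ln t; δ_l) x_l

with `x` containing deprivation dummies, a restricted cubic spline of age
at diagnosis and their interaction; the `s_l` terms make the deprivation
and age effects time-dependent.  Then

    λ_E(t|x) = Λ_E(t|x) · (∂η/∂ ln t)/t ,   R(t|x) = exp(−Λ_E(t|x)) ,

and the all-cause hazard is `h*(t) + λ_E(t|x)`.  Fitting is maximum
likelihood on a **period analysis** dataset (delayed entry at the window
start, censoring at the window end), so the estimates reflect recent
patient experience.  Because the spline tails are linear in `ln t`, `R`
extrapolates with a Weibull-like tail beyond follow-up — the ingredient
that makes life-time extrapolation of `S*·R` stable, since the expected
hazard dominates at long times.  All integrals are computed exactly per
piecewise-constant segment of the life table (Gauss–Legendre inside each
segment for the `R` factor).

## Worked example

Everything below runs in a few seconds from a fresh checkout; there is no
data to download because the synthetic module generates a registry with the
full deprivation structure (and exact ground truth, used by the test
suite).

```python
from lifelost import (FitConfig, FlexParamRelSurv, Profile, default_scenario,
                      make_life_table, simulate_registry, first_tumour_filter,
                      make_period_dataset, summary_table)

config = default_scenario(seed=20130101)
registry = simulate_registry(config)          # ~100k diagnoses, 1998-2013
table = make_life_table(config)               # deprivation-graded life table
period = make_period_dataset(first_tumour_filter(registry))  # window 2007-2013

model = FlexParamRelSurv(period, table,
                         FitConfig(df_baseline=4, df_age=2, td=(), interaction=False))
results = model.fit()

patient = Profile(age_at_diagnosis=70.0, sex="F", deprivation=5,
                  diagnosis_date=2013.0)
print(results.life_expectancy(patient))

summary = summary_table({("siteA", "F"): results}, table, registry)
print(summary.round(3).to_string(index=False))
```

Output:

```
E*=13.89y  E=2.15y  LEL=11.75y  PLL=84.6%
cancer sex  deprivation  mean_lel  mean_pll  n_ref_year  total_years_lost
 siteA   F            1    13.471     0.654        1283         17283.290
 siteA   F            2    12.094     0.668        1256         15189.972
 siteA   F            3    11.261     0.684        1204         13557.976
 siteA   F            4    11.066     0.707        1231         13622.059
 siteA   F            5    12.381     0.838        1244         15401.498
```

Reading this: a 70-year-old woman in the most deprived quintile diagnosed
in 2013 would expect 13.9 more years without the cancer but only 2.2 with
it — a loss of 11.7 years, 84.6% of her remaining life.  The standardised
summary shows the least deprived losing the most absolute years (13.5 on
average — they have the most years to lose) while the proportion of life
lost rises steadily with deprivation (65% → 84%); multiplying each group's
2013 diagnosis count by its mean loss gives the total population burden.

The same pipeline is scriptable:

```sh
lifelost simulate --scenario default --seed 20130101 \
    --registry reg.csv --lifetable lt.csv
lifelost prepare reg.csv --window 2007:2014 --out prep.csv
lifelost fit --prepared prep.csv --lifetable lt.csv --df 5 --td-df 3 --out m.json
lifelost predict-lel --model m.json --lifetable lt.csv --age 70 --dep 5 --sex F
lifelost run --config pipeline.yaml --out artifacts/   # the whole thing
```

Life tables are CSVs with columns `sex,dep,age,year,rate` (annual hazards;
complete over sexes × quintiles 1–5 × ages 0–99+ × the year range;
`lifelost lifetable validate` checks this).  Registries are CSVs with
columns `id,cancer,sex,dep,age_dx,date_dx,date_exit,event`; dates are
decimal years.

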