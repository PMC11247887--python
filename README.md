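# previnc

**Chronic-disease incidence back-calculated from repeated cross-sectional
prevalence surveys, via the illness-death model.**

Longitudinal cohorts are the textbook way to measure an incidence rate, but
for many countries none exist at national scale. What often does exist is a
sequence of cross-sectional health surveys (prevalence by age and sex, every
few years) and vital statistics (all-cause mortality by age, sex and year).
`previnc` turns those two ingredients — plus an assumed mortality rate ratio
between diseased and disease-free people — into age- and sex-specific
incidence rates with resampling confidence intervals. The motivating
application is self-reported diabetes in adults (ages 20–79) measured by
national surveys repeated every six years, but nothing in the package is
specific to diabetes.

## The model

The three-state illness-death model (healthy → diseased → dead, healthy →
dead, no remission) implies a partial differential equation for prevalence
*p*(*a*, *t*) over age *a* and calendar time *t*. Solving it for the
incidence rate *i* gives

```
        (∂/∂a + ∂/∂t) p        p (MRR − 1)
  i  =  ───────────────  +  m ───────────────
            1 − p              p (MRR − 1) + 1
```

where *m* is general-population mortality and MRR the mortality rate ratio
(diseased vs disease-free), assumed log-linear in age between two anchor
ages (30 and 80 years). The derivative (∂/∂a + ∂/∂t)*p* is the change of
prevalence along a birth cohort, which is identifiable from at least two
cross-sections; incidence is estimated midway between consecutive survey
waves (e.g. waves 2000/2006/2012/2018 → estimates for 2003, 2009, 2015).

The estimation chain is:

1. **Per-wave prevalence fit** — survey-weighted logistic regression of the
   disease indicator on a natural cubic spline in age (five equally spaced
   interior knots), per sex (`fit_wave`).
2. **Pooling** — the per-wave fitted logit prevalences are regressed on a
   cubic B-spline in age (3 interior knots) × linear survey year × sex with
   the full three-way interaction, giving one smooth logit surface with a
   coefficient covariance (`pool_waves`).
3. **Inversion** — the identity above is evaluated at each age with the
   surface's analytic directional derivative, interpolated mortality and
   the MRR profile (`estimate_curve`).
4. **Uncertainty** — 2,000 resampling replicates: each draws surface
   coefficients from their sampling distribution and MRR anchors from
   uniform plausibility ranges (7.5–8.5 at age 30, 2.5–3.0 at age 80);
   rates, standardized rates and incidence rate ratios are computed per
   replicate and summarized by 2.5/50/97.5 percentiles (`resample`).
5. **Reporting** — 10-year age-group rates evaluated at the group midpoint
   (55 for 50–59), directly age-standardized rates, and IRRs between years,
   per 1,000 person-years (`report_table`).

A forward solver (`solve_prevalence_forward`) integrates the same PDE along
cohort characteristics, so fully synthetic surveys and mortality schedules
with known ground truth are available for validation (`make_default_scenario`,
`generate_survey`, `generate_mortality_schedule`).

## Worked example

```python
import pandas as pd
import previnc as pv

scenario = pv.make_default_scenario(seed=42)
truth = pv.scenario_truth(scenario)
waves = [pv.generate_survey(scenario, year, n=10_000, seed=42 + k, truth=truth)
         for k, year in enumerate(scenario.wave_years)]
surface = pv.pool_waves([pv.fit_wave(w) for w in waves])
mortality = pv.generate_mortality_schedule(scenario)
std = pv.StandardPopulation.from_survey(pd.concat(waves, ignore_index=True))
years = pv.midpoint_years(scenario.wave_years)          # (2003.0, 2009.0, 2015.0)
result = pv.resample(surface, mortality,
                     pv.ResamplingConfig(repetitions=2000, seed=42), years, std)
for sex in ("male", "female"):
    for year in years:
        lo, med, hi = result.standardized_band(sex, year) * 1000
        print(f"{sex:6s} {year:.0f}  IR {med:5.2f} (95% CI {lo:.2f}-{hi:.2f}) per 1000 pryr")
irr = pv.incidence_rate_ratio(result, 2015.0, 2003.0)
for sex, d in irr.items():
    print(f"{sex:6s} IRR 2015 vs 2003: {d['irr']:.2f} ({d['lo']:.2f}-{d['hi']:.2f})")
```

prints

```
male   2003  IR  5.69 (95% CI 5.12-6.27) per 1000 pryr
male   2009  IR  6.58 (95% CI 5.87-7.29) per 1000 pryr
male   2015  IR  7.55 (95% CI 6.47-8.67) per 1000 pryr
female 2003  IR  5.81 (95% CI 5.22-6.45) per 1000 pryr
female 2009  IR  6.54 (95% CI 5.82-7.33) per 1000 pryr
female 2015  IR  7.35 (95% CI 6.29-8.55) per 1000 pryr
male   IRR 2015 vs 2003: 1.33 (1.17-1.50)
female IRR 2015 vs 2003: 1.26 (1.11-1.44)
```

The age-standardized incidence rate (IR) is the weighted mean of 10-year
age-group rates, weighted by the pooled sample's own age distribution; the
IRR is the replicate-wise ratio of standardized rates between two
estimation years. Here the synthetic ground truth has incidence rising
~1.5–1.8%/year, and the recovered IRs and IRRs track it within sampling
noise at n = 10,000 per wave.

The same pipeline is available from the shell:

```sh
previnc run-all --config my_config.yaml --out results/
```

with subcommands `simulate`, `fit`, `estimate` and `report` for the
individual stages; real survey/mortality/standard-population data can be
supplied as CSV files (see `previnc/default_config.yaml` for the dialects
and keys).

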