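# Methods

This note records the modelling choices behind `previnc`: the governing
equations, the estimation chain, the synthetic ground truth used for
validation, numerical details, and known limitations. It documents how
results are computed, not what their values are — every number cited in the
README is printed by the code itself.

## Illness-death model and the inversion identity

The population is partitioned into healthy, diseased and dead, with
transitions healthy → diseased (incidence *i*), healthy → dead (rate *m₀*)
and diseased → dead (rate *m₁* = MRR · *m₀*). The disease is treated as
irreversible: no remission transition exists, so the model fits conditions
like diagnosed diabetes and not, say, depression. Under this model the
prevalence field *p*(*a*, *t*) obeys a PDE whose characteristic curves are
birth cohorts (*t* − *a* constant). Along a cohort,

    dp/da = (1 − p) · [ i(a, t) − p · m₀(a) · (MRR(a) − 1) ].

Re-expressed with the *general-population* mortality
*m* = *m₀*·(1 + *p*(MRR − 1)) — the mixture actually observed in vital
statistics — and solved for *i*, this becomes the inversion identity

    i = dp/(1 − p) + m · p(MRR − 1) / (p(MRR − 1) + 1),

with dp the cohort (directional) derivative (∂/∂a + ∂/∂t)p. The package
keeps both forms: `eval_incidence_equation` / `eval_pde_rhs` are exact
algebraic inverses of each other (property-tested), and the forward solver
parameterizes mortality by *m₀* while emitting the implied *m*, so the
simulator produces exactly the mortality input the estimator expects.

Negative incidence estimates can arise when prevalence declines faster
than differential mortality explains. They are returned as computed and
flagged, never truncated: truncation would bias the resampling percentiles
whose lower bounds legitimately approach zero.

## MRR profile

No representative MRR data accompany the survey inputs, so the MRR enters
as an assumption: log(MRR) affine in age between two anchors, by default
ages 30 and 80. Outside the anchor interval the profile is clamped to the
nearest anchor value; extrapolating the log-line below age 30 would give
implausibly large ratios at age 20. Plausibility ranges for the anchors
(7.5–8.5 at 30, 2.5–3.0 at 80) feed the resampling; the point profile uses
the range midpoints (8.0 and 2.75).

## Two-stage prevalence smoothing

**Stage 1 (per wave, per sex).** Weighted maximum-likelihood logistic
regression of the disease indicator on a natural cubic spline in age.
"Five equally spaced knots" is implemented as five equally spaced
*interior* knots with boundary knots at the ends of the age range (the
`ns(x, knots=...)` convention); the count and placement are configurable.
Survey weights enter as likelihood weights and are normalized to unit mean
(the MLE is invariant to weight scale; normalizing makes that exact at
optimizer tolerance). Weight handling is weights-only: stratum/PSU
linearization is out of scope, and uncertainty is instead propagated
through the model-based covariance below.

**Stage 2 (pooling).** The stage-1 fitted logit prevalences, evaluated at
every integer age for each sex and wave, are stacked and regressed by OLS
on a tensor design: cubic B-spline in age (3 interior knots at the
quartiles of the age grid) × {1, centred survey year} × {1, sex}, i.e. the
full age × year × sex interaction. The fitted surface returns prevalence
via the inverse logit, and its age/year derivatives are analytic (B-spline
derivative basis; the linear year factor differentiates to a constant).
A central finite difference along the cohort diagonal (step 0.1 years) is
provided as a cross-check and agrees with the analytic derivative to
second order.

**Coefficient covariance.** The resampling draws surface coefficients from
a multivariate normal. Its covariance is, by default, the exact
delta-method propagation of the stage-1 GLM coefficient covariances
through the stage-2 linear map: Cov = A · blockdiag(G Covₖ Gᵀ) · Aᵀ, with
A = (XᵀX)⁻¹Xᵀ the stage-2 projector and G the stage-1 basis on the age
grid. This is the sampling distribution of the input prevalence itself,
which is what the resampling is meant to propagate. The alternative
(`cov_mode="ols"`), the stage-2 residual-based OLS covariance conditional
on stage-1 point estimates, reflects only smoothing-residual scatter and
understates survey sampling noise by a large factor — it is kept as an
option, not the default. A per-wave precision weighting of the stage-2
rows (`precision_weighted`) exists and is off by default.

**Age convention.** Records code age in completed years; all continuous
evaluations use age + 0.5, the cell centre, so discrete records and the
continuous model agree without a systematic half-year offset.

## Incidence pipeline

Incidence is estimated at the midpoints of consecutive wave pairs — the
years at which a symmetric two-cross-section contrast identifies the
cohort derivative. Reporting follows three rules, each pinned for
reproducibility:

* **Age groups**: 10-year groups 20–29 … 70–79, each evaluated at the
  group midpoint (25, 35, …, 75).
* **Standardization**: direct, i.e. a normalized-weight sum of group
  rates. The default standard population is the pooled survey's own
  weighted age distribution; any standard can be supplied as CSV. The
  choice of standard materially shifts the level of "the" standardized
  rate, which is why it is explicit configuration and recorded in the run
  metadata.
* **Percentiles**: linear interpolation between order statistics
  (`numpy` "linear"), applied cell-wise over replicates. Point estimates
  are replicate medians; a plug-in (no-noise) estimate is also stored.

Each resampling replicate draws one coefficient vector and one MRR
profile (anchors drawn independently from their uniform ranges; a
common-quantile mode couples them), then evaluates the full curve, group
rates, standardized rates, and IRRs *within the replicate*. Ratios with a
non-positive denominator are excluded from the IRR percentiles with a
recorded count; if every replicate is excluded the IRR is reported as
undefined (NaN) rather than failing the run. Rates are stored per
person-year internally; the ×1000 scale appears only in reports.

## Synthetic ground truth

The default scenario emulates the structure of the motivating study:
four survey waves (2000, 2006, 2012, 2018) of 44,000 persons each, ~50%
women, ages 20–79 drawn from an exponentially tilted adult age pyramid
(rate 0.035/year, so ~60-year-olds are about a quarter as frequent as
20-year-olds), log-normal unit-mean sampling weights (σ = 0.5), and
self-reported-diagnosis-style binary disease drawn at the forward-solved
true prevalence. True incidence rises to a peak of 18–19 per 1,000
person-years near age 65 then declines (Gaussian shape, width 16 years),
with a mild linear calendar trend of +1.5%/year (men) and +1.8%/year
(women) relative to 2009; "mild" here means small enough that the pooled
model's linear-year logit structure can track it, which is the regime the
two-stage smoother is designed for. Disease-free mortality is Gompertz
(α·e^(βa), α = 9×10⁻⁵/6×10⁻⁵, β = 0.085/0.088 for men/women), giving
adult mortality and ~15–20% prevalence at age 60 on the scale of the
motivating population. Weights are non-informative by default; an
informativeness knob multiplies diseased persons' weights by a constant
factor for bias studies. Cluster/stratum structure is not simulated —
uncertainty propagation operates on the fitted prevalence distribution,
not on design-based replication.

What passing tests on this generator do *not* show: robustness to
informative nonresponse, misclassification of self-report, undiagnosed
disease, migration, or real-world departures of the logit surface from
the pooled model span. The noise-free recovery error (~3%) reported by
the acceptance script is the method's intrinsic smoothing bias under
these conditions, separate from sampling noise.

## Numerical choices

* Characteristic ODE integration: adaptive DOP853 with rtol = atol =
  10⁻¹⁰; initial condition p = 0 at age 0 (prevalence at birth ≈ 0 for
  adult-onset disease). All requested (age, year) cells are integrated as
  one stacked system with dense output.
* The linear predictor is capped at |η| ≤ 35 before inverse-logit so
  prevalence stays strictly inside (0, 1) in double precision even for
  extreme coefficient draws.
* Stage-1 IRLS: tolerance 10⁻¹⁰, up to 300 iterations. With sparse
  young-age cases the likelihood can be near-flat (quasi-separation) and
  the optimizer may stop unconverged; fitted grid values remain stable
  but single-class data raise an error naming the wave and sex.
* Rank deficiency of the pooled design raises an error listing aliased
  columns; covariance matrices are validated symmetric PSD at surface
  construction (eigenvalue floor −10⁻¹⁰ relative).
* CSV floats are read with round-trip precision so written results
  re-read bit-exactly; fixed seeds make the whole pipeline byte-identical
  across runs.

## Problem sizes used in the test suite

Validation scales are chosen to separate concerns: the inversion oracle
runs on an exact 0.25-year grid (no sampling); smoother recovery uses
4 × 100,000 records; end-to-end recovery uses the full 4 × 44,000 survey
scale with 500 replicates; coverage uses 100 replications of 4 × 20,000
with 200 replicates each. The coverage check and the end-to-end check
each complete in about a minute on one CPU.

## Known limitations

* The smoother's linear-year logit structure biases the cohort derivative
  at estimation years far from the study midpoint when the true trend is
  strongly nonlinear on that scale; the noise-free recovery error
  quantifies this for the default scenario.
* At the oldest ages (≥ ~76) the tilted age pyramid leaves few records
  and fitted prevalence is noticeably noisier; the smoother's pointwise
  prediction SE on the probability scale there is ~0.01 at n = 100,000
  per wave, which bounds how tightly any recovery of old-age prevalence
  can be asserted.
* MRR is an assumption, not an estimate; results should be read as
  conditional on the anchor ranges.
* The two mortality inputs (schedule and MRR) are treated as known up to
  the sampled ranges; vital-statistics sampling error is not modelled.
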