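# Methods

This note records the modelling choices behind `hearburden`: what each stage
assumes, the defaults and why, what the synthetic world does and does not
emulate, and the numerical conventions.

## Severity taxonomy

Hearing loss is the better-ear pure-tone average over 0.5/1/2/4 kHz.  The
printed integer dB bands ("20–34 dB") are implemented as half-open real
intervals [20, 35) so classification is total and unambiguous on continuous
pure-tone averages; whether a measurement of exactly 35.0 dB is mild or
moderate is a convention (we take the inclusive lower bound), and nothing
downstream is sensitive to it at the resolution of survey data.  "All
hearing loss" is every category from 20 dB; "moderate-to-complete" every
category from 35 dB.  Disability weights (13 health states: normal plus six
severities × with/without tinnitus) ship as a packaged TSV and can be
overridden; weights are fractions of a year of perfect health lost per year
lived in the state.

## Synthetic world

The generator is the package's study population, not a test fixture.  Its
structure:

- **Any-loss prevalence** follows a logistic curve in age: intercept −3.2,
  slope 0.065 per year above age 25, plus a small early-childhood bump
  (0.4 on the logit scale, Gaussian in age with scale 5 years).  This gives
  ≈2–4% loss in early adulthood rising steeply after age 50 to ≈75–80% at
  the oldest ages — the qualitative age profile of audiometric surveys.
- **Moderate-plus share within loss** is likewise logistic (intercept −1.6,
  slope 0.022 above age 30, childhood bump 1.0), so severity worsens at the
  age extremes; the conditional split across the five severities uses fixed
  base shares (0.655, 0.210, 0.055, 0.047, 0.033 — roughly the observed
  global composition of moderate-plus loss) tilted toward the severe end in
  early childhood and old age.
- **Covariates.** Each location carries an SDI-like development index in
  [0, 1] (region-structured, drifting upward 0.004/year) entering the
  any-loss logit with coefficient −0.6, and an HAQ-like index = 15 + 75·SDI
  + noise, clipped to [0, 100].  Development therefore lowers loss and the
  two covariates are strongly correlated, which is what gives the HAQ
  regression its negative slope.
- **Random effects**: region intercepts (SD 0.25) and location intercepts
  (SD 0.12) on the logit scale; male−female difference 0.12.
- **Hearing-aid coverage** rises with severity (0.05 mild → 0.33 complete);
  **tinnitus co-occurrence** rises from 0.25 (mild) to 0.50 (profound,
  complete).  Both are constant in age — a simplification the coverage
  model does not assume.
- **Causes.**  Age-varying mixture with under-5 fractions
  (congenital 0.25, otitis media 0.637, meningitis 0.08, other 0.033)
  decaying exponentially while age-related/other saturates; at ages 50–54
  the age-related/other fraction is ≈0.97.  Severity is independent of
  cause within an age group, matching the tinnitus assumption that the
  ringing share is cause-invariant.
- **Microdata.**  A person's severity category is multinomial with the
  stratum's true prevalences; the pure-tone average is then drawn within
  the category's band (beta-shaped, right-skewed; exponential tail above
  95 dB).  Category mass therefore matches the truth exactly in
  expectation, while within-band placement is a modelling convenience that
  only the crosswalk oracle depends on (and it uses the same beta tail).
- **Population**: exponential age pyramid whose age scale grows 0.35
  years per calendar year and whose total grows 1.3%/year — so later years
  are larger and older, reproducing the regime where stable age-specific
  rates still produce rising crude prevalence.
- The default world is 6 regions × 3 locations × 7 years (1990–2019) ×
  2 sexes × twenty 5-year age groups.

What it does **not** emulate: audiometer measurement error, unilateral
loss, conductive vs sensorineural distinctions, geographic variation in
tinnitus, survey nonresponse, or cause-severity dependence.  Passing tests
therefore demonstrate the correctness and calibration of the estimation
machinery under its own assumptions, not the field accuracy of any real
survey system.

## Harmonisation

The meta-regression surrogate is an inverse-variance weighted mean with
one-pass trimming (default 10%, dropping the most discrepant pairs in
standardised units) and DerSimonian–Laird between-study heterogeneity.  Sex
ratios are estimated per 5-year age group with a pooled fallback; the split
of a both-sex row solves p_f = r·p_m subject to the population-weighted
mean equalling the observed prevalence, and deflates each output's
effective sample size by the delta-method variance of the ratio.
Crosswalk coefficients are mean logit differences over (sex, age) cells of
microdata, with the reference range chosen by snapping the alternative
range's endpoints to the nearest scheme boundaries; prevalences of exactly
0 or 1 receive a half-case continuity offset p ← (x + 0.5)/(n + 1) before
the logit.  Age splitting applies only to spans strictly wider than 20
years and conserves expected cases exactly.

## Prevalence models and squeezes

Each category model is a weighted least-squares regression of logit
prevalence on a cubic B-spline over age (default 10 basis functions over
0–100; enough to resolve the early-childhood curvature that a 6-function
basis visibly underfits) plus the SDI-like covariate, weighted by the
delta-method precision n·p·(1−p).  The covariate coefficient is
sign-constrained (non-positive for loss categories, non-negative for the
no-loss category): if the unconstrained fit violates the sign, the
covariate is dropped rather than allowed a perverse slope.  Location random
intercepts are estimated by shrinking per-location weighted residual means;
residual heterogeneity τ² (a DL-style moment estimate) is added to every
cell's predictive variance so that lack of spline fit widens the intervals
instead of silently biasing them.  Draws are sampled from the asymptotic
normal of the coefficients plus location-effect and τ² noise; D = 1000 by
default (runs in this repository use 100–500 where only determinism or
conservation is at stake).

The top-level squeeze divides (no loss, mild, moderate-plus) by their sum
per cell and draw; the severity squeeze scales the five severities to the
envelope.  Cells where all five sub-models are zero but the envelope is
positive fall back to the five models' global mean shares (logged).  Both
squeezes are exact: post-squeeze sums match their targets to machine
precision.

## Hearing-aid shift

Coverage is fitted per severity (logit-scale age spline, pooled over
geography — coverage data are far too sparse for geographic structure),
with two priors: severities with no data borrow the next-lower severity's
fit, and draws are made non-decreasing in severity by a running maximum.
The shift computes all outflows from the unadjusted surface simultaneously
and moves each severity's aided share one category down, aided mild joining
"no loss".  It is a single reclassification — deliberately not iterated —
and a provenance flag on the surface makes a second application an error.
Conservation of the all-category sum is exact.

## Cause attribution and tinnitus

Below the age cutoff (default 20 years) all four causes are proportionally
rescaled to each severity's total; above it the three named causes are kept
and the residual goes to age-related/other.  A negative residual (named
causes exceeding the total, which happens readily for rare severities
estimated from small samples) is resolved by rescaling the named causes to
the total and zeroing the residual, with a count of affected cell-draws
surfaced.  In the pipeline the per-cause input surfaces come from microdata
tabulations with a quarter-pseudo-case prior spread over the age group's
pooled cause fractions, so the under-cutoff squeeze always has mass to
rescale.  The under-20 squeeze is applied per severity.

Tinnitus proportions are binomial estimates per (severity, age group, sex)
among records ≥ 20 dB, pooling sparse strata first over sex, then over
adjacent age groups, then to the severity total (denominator threshold 25).
The split samples the proportion per draw from its normal approximation
truncated to [0, 1]; the same draw is used across causes, making the
ringing share cause-invariant and the two states exactly additive.

## Burden

YLD rate = prevalence × disability weight per state and draw; counts
multiply by population.  Disability-weight uncertainty is propagated by
sampling each weight per draw from a logit-normal matched to its printed
95% interval (toggleable, default on).  Intervals follow the ordered-draw
convention: nearest-rank 2.5/97.5 percentiles, which at D = 1000 are
exactly the 25th and 975th ordered draws.  Aggregation sums counts at draw
level before summarising.  Age standardisation uses a packaged WHO World
Standard-style weight table by default, but every internal calibration
check uses the synthetic world's own population-derived standard so that
nothing depends on external weights.  Percent changes are computed per draw
and then summarised; on point estimates the same arithmetic is exposed
directly (draw-level means can differ from point-estimate arithmetic in the
last printed digit — both are available rather than forced to agree).
The report table rounds cases to 0.1 million and prints envelope rows as
sums of the rounded severity rows, so the displayed table is additive by
construction.

## Forecasting

The projection regression runs per sex on the logit of age-specific
regional prevalence rates with year (centred), region, region×year and a
cubic B-spline in age (knots at quantiles of the age grid).  The logit link
keeps every predicted rate in (0, 1), so the negative-rate clip counter
exists only for audit and stays zero.  "Run 1000 times" is implemented as a
residual bootstrap: residuals are resampled with replacement, the model is
refitted, and each coefficient set predicts 2030/2040/2050 rates that are
multiplied by the forecasted population and aggregated to regional and
global case draws.  With constant input rates the projection is flat; with
stable rates and an ageing population crude prevalence rises while the
age-standardised rate is flat — both identities are tested.

## Pipeline, determinism and problem sizes

Stage order: simulate → process → estimate → adjust → causes → tinnitus →
burden → forecast.  All randomness derives from the run seed through fixed
per-stage offsets; identical configurations produce byte-identical output
tables (checksummed in the run manifest).  To keep the demonstration runs
desk-scale, the repository's tests use a 2-region world with 100 draws and
a few hundred records per stratum, while the parameter-recovery study uses
a single-location world with 50 000 records per stratum, 1000 draws and ten
replicates — large enough that interval coverage is a meaningful
calibration measurement (≈95% observed across severity prevalence,
coverage, tinnitus and the under-5 otitis share).

## Known limitations

- The estimation surrogates are regression approximations of full Bayesian
  meta-regression tools; they share inputs and outputs but not internals
  (no incidence/remission consistency, no MCMC posterior).
- Cause attribution above age 20 is a residual: anything not named becomes
  age-related/other, and negative residuals are resolved by rescaling.
- The crosswalk assumes the microdata represent the populations whose rows
  are being adjusted; like the source method, it ignores geographic
  variation in threshold distributions.
- The hearing-aid shift is a uniform one-category reclassification; partial
  benefit and device quality are not modelled.
- Forecast uncertainty reflects regression residual bootstrap only, not
  uncertainty in the input prevalence surfaces or the population forecast.
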