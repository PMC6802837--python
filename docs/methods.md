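# Methods

## The model

`flsim` implements a discrete-time, individual-level state-transition
(microsimulation) model of hepatic steatosis ("fatty liver", diagnosed by
ultrasonography) in adult men.  The disease state is binary.  For member
*i* the probability that fatty liver is present at year *t+1* is a
main-effects logistic in three binary predictors measured at year *t*:

```
logit P(FL_{t+1} = 1) = beta0 + beta_fl * FL_t + beta_bmi * [BMI_t >= 25] + beta_ratio * [LDL_t/HDL_t >= 2]
```

There are no interaction terms, so the model is fully described by the
8-cell transition table it induces.  The published table is

| FL | BMI>=25 | ratio>=2 | P(present next year) |
|----|---------|----------|----------------------|
| 0  | 0       | 0        | 0.031 |
| 0  | 0       | 1        | 0.074 |
| 0  | 1       | 0        | 0.072 |
| 0  | 1       | 1        | 0.164 |
| 1  | 0       | 0        | 0.649 |
| 1  | 0       | 1        | 0.823 |
| 1  | 1       | 0        | 0.819 |
| 1  | 1       | 1        | 0.919 |

and is embedded as `PUBLISHED_TRANSITION_TABLE`.  An unweighted
least-squares fit of the cell log-odds on the intercept plus three binary
indicators (`fit_table_main_effects`) reproduces every cell to better than
0.0005, i.e. the table is additive on the logit scale; the implied
coefficients are (-3.445, 4.061, 0.893, 0.921).  Unweighted least squares
is the only available reconstruction because per-cell sample sizes are not
published.  Persistence is far below 1 (cell 1,0,0 -> 0.649), so the model
reproduces the clinical observation that fatty liver is reversible.

With covariates frozen, each member is a two-state Markov chain with
incidence `p01` and persistence `p11`; its long-run prevalence is the fixed
point `p01 / (p01 + 1 - p11)` (`stationary_prevalence`).  This closed form
is the simulator's analytic oracle: 0.0812 for the all-normal cell pair and
0.6694 for the all-abnormal incident cell pair.

## Annual covariate updates

Only the two covariates in the transition model are advanced: BMI and the
LDL-C/HDL-C ratio.  Each follows a first-order autoregression with age
terms, fitted by OLS on consecutive-year pairs:

```
v_{t+1} = intercept + slope * v_t + a1 * age + a2 * age^2 + N(0, sd)
```

BMI is modelled on the natural scale.  The cholesterol ratio is modelled on
the **log** scale (same equation in `log v`): the ratio is a positive
quotient with multiplicative noise, and iterating a homoscedastic
linear-scale Gaussian residual measurably inflates the ratio>=2 prevalence
over a multi-decade horizon (a few percentage points by year 4, enough to
leave the +/-2 SD calibration band), while the log-scale form stays
calibrated.  The residual SD uses the usual degrees-of-freedom correction.
During simulation, residual draws are resampled into physiologic bounds
(BMI in [12, 60] kg/m2, ratio in (0, 10]) so 40-year projections cannot
drift to impossible values.

The exact update equations used in the original analysis are unpublished;
this AR(1)-plus-age-terms form is the simplest rule consistent with
"stochastic prediction from regression on the prior year", and it is fitted
from data rather than assumed.  Lifestyle booleans and the covariates that
were eliminated from the transition model are carried forward unchanged.

## Monte Carlo projection protocol

`simulate_lifecourse` advances a closed cohort (no entry, exit or death)
year by year: covariate update, risk-flag recomputation, then a Bernoulli
draw at the transition probability of the member's **pre-update** cell
(the table is defined on the predictors before transition, and the fitting
regression is V(t) -> FL(t+1), so using time-t flags makes simulating with
the generating model exactly self-consistent).  The projection runs until
the cohort mean age reaches 75 (midpoint of the 70-79 band) unless an
explicit horizon is given.

The protocol is 10 replicate runs from the same baseline; the reported
trajectory is the across-run mean and the uncertainty band is +/-2 SD
across runs ("Monte Carlo variation").  Replicate *r* of a projection with
seed *s* uses `default_rng([s, r])`, so projections that differ only in a
perturbation share random streams (common random numbers): the baseline
contrast at zero perturbation is exactly zero and Monte Carlo noise largely
cancels from sensitivity contrasts.

Sensitivity perturbations multiply each year's predicted (pre-residual)
covariate value by `1 + delta`, compounding over the horizon (on the log
scale the equivalent `log(1+delta)` shift is added).  Perturbing the
realized value including the residual, or the regression coefficients, are
deliberate non-defaults; the compounding-prediction semantics is what makes
update perturbations grow in impact over the projection while
initial-composition changes decay.

## Synthetic study population

No public individual-level dataset exists for the modelled population, so
`generate_population` creates panels with the documented structure of the
study data, and every downstream stage is developed and tested against
them.  Key choices:

* **Marginals.**  BMI and TG are right-skewed (shifted lognormal); BMI's
  shape parameter is solved so that the configured mean/SD coexist with the
  configured BMI>=25 fraction (23.3 / 3.6 / 27% for the youngest projection
  cohort — a symmetric normal would give ~32%).  LDL and HDL are bivariate
  normal with correlation -0.2 so that the ratio>=2 fraction (~53-57%) is
  attainable; the ratio itself is always computed, never generated.  The
  true cross-correlation structure of the study population is unpublished;
  these are flagged stand-ins in the config.
* **Age profiles.**  Each covariate's long-run mean follows a
  piecewise-linear age profile: BMI rises to ~24 in the 40s-early 50s and
  declines toward ~21.5 by the late 70s, LDL peaks in the 40s and declines
  after 60, consistent with Japanese national survey patterns.  This
  profile is what gives the simulated life-course its documented unimodal
  shape (prevalence peaking while the cohort is 40-59 and lower by 70-79).
* **Dynamics.**  AR(1) persistence toward the age profile: BMI rho 0.95
  with residual SD 0.8 (adiposity tracks tightly year to year); lipids,
  pressure and glycemia rho 0.85-0.90 with correspondingly larger residuals.
  The persistence asymmetry is also why a multiplicative update
  perturbation moves the life-course several-fold more through BMI than
  through the cholesterol ratio — the central comparative finding.
* **Disease state.**  At entry each member receives one Bernoulli draw at a
  logistic in their dichotomized covariates whose covariate part is the
  stationary log-odds of their transition-table cell, plus a single
  intercept shift solved so the realized baseline prevalence matches the
  configured target (19.8% for the 30-39 cohort, 27% population-wide).
  Anchoring entry status near the dynamics' steady state keeps the
  generated population's age-prevalence profile consistent with the
  transition model, which is what makes time-shift consistency of
  differently-aged cohorts a property of the process rather than an
  artifact of burn-in.  Thereafter status evolves by the configured
  transition model applied to the time-t flags.
* **Open population.**  9%/yr enrollment, 6%/yr attrition; lifestyle
  booleans are drawn once per person and held fixed (no transition rules
  exist for them).
* **Missingness.**  Ultrasonography availability by age band (0% at 20-29,
  9.1% at 30-39, 95.5% at 40+) is applied as exact per-band thinning with a
  seeded RNG.

What the generator does **not** emulate: the joint distribution of the real
data beyond first/second moments and category fractions, covariate
cross-correlations other than LDL-HDL, secular trends, measurement error in
ultrasonography, and mortality.  Tests passing on synthetic panels
therefore show that the pipeline is internally correct and recovers known
generating structure — not that the fitted numbers would match the original
cohort's.

## Fitting pipeline

* The transition model is fitted by logistic regression of observed status
  at t+1 on status and candidate flags at t, with backward elimination
  (drop the largest p >= 0.05, one per step, ties broken by term order;
  current status is always retained).  On faithful panels the BMI and ratio
  flags survive and the other seven candidates are eliminated.
* Transitions are fitted on **observed** statuses only.  Imputed statuses
  are cross-sectional Bernoulli draws with no year-to-year dependence;
  including them attenuates the persistence coefficient severely (measured:
  beta_fl 2.2 instead of 4.1 when ~36% of person-years are imputed), so
  imputation is used only to complete simulation baselines.
* Missing statuses are imputed from a same-year logistic model (BMI flag,
  ratio flag, age) fitted on observed records aged 30-69; observed statuses
  are never altered, and the imputation is deterministic given its seed.
  Whether the original imputation also used lifestyle terms is unknown; the
  covariate list is configurable.
* Fewer than 50 transitions (or pairs) and complete separation are rejected
  with diagnostics rather than returning unstable estimates.

## Validation and sensitivity protocol

* **V-1 calibration:** the complete-case cohort (members present in every
  wave with no missing fields — a closed simulation is only comparable to
  members observed throughout) is simulated over its own observation years;
  each observed prevalence (fatty liver, BMI>=25, ratio>=2) is checked
  against the +/-2 SD band.  The pass rule is coverage in >= 80% of
  quantity-years: with 10 runs the band is a rough estimate, and an
  every-year-every-quantity rule would fail a non-negligible fraction of
  perfectly calibrated replicates.
* **V-2 time-shift:** cohorts with baseline ages 30-39, 40-49, 50-59 are
  projected to 70-79 and aligned on decade bands; overlap in a shared band
  means |mean_A - mean_B| <= 2 (SD_A + SD_B) — a conservative, assertable
  formalization of "the trajectories almost overlapped".
* **V-3 external:** band-level comparison against user-supplied prevalence
  tables from other populations (configured, never bundled); the report
  gives the difference and whether the simulated mean lies inside the
  external min-max range.
* **S-1 initial composition:** stratified resampling with replacement moves
  one risk category's baseline prevalence by +/-20/40% while leaving other
  marginals disturbed only through resampling.  The headline change is read
  at the 50-59 band in percentage points; year-5 and final-year changes are
  also recorded.  For axes outside the transition model the discriminating
  statistics are the early-projection and 50-59-band changes: the
  max-over-years |change| has a 0.8-1.6 pp noise floor at 10 runs even for
  a null resampling (the resampled member set consumes different random
  numbers), so it cannot distinguish a no-effect axis from nothing.
* **S-2 update perturbation:** deltas of +/-0.5% and +/-1% per year,
  paired seeds, changes reported in the published four-column layout.
  Whether the maximum change should be signed or absolute is ambiguous;
  absolute is implemented.

## Problem sizes and determinism

The test suite fits on panels of ~3000 persons x 5 waves (~12k
person-transitions) and projects cohorts of ~2000 members for ~40 years
with 10 runs; the full `run_study` driver uses 2000 persons per wave.
These sizes make every stochastic check's tolerance derivable from a
standard-error argument (3 SE rules throughout) while keeping the whole
pipeline runnable in seconds to minutes.  All randomness flows through
`numpy.random.default_rng` seeded from explicit integers; every public
entry point takes a seed, and identical seeds give byte-identical outputs.

## Known limitations

* Closed population: no mortality, so old-age prevalence is overstated
  relative to an open population (a stated limitation of the original
  analysis as well).
* The Gaussian AR update is a stand-in for unpublished update equations;
  the linear-scale form visibly miscalibrates the ratio flag over decades
  (see above), and even the log-scale form is only an approximation to the
  generator's quotient dynamics.
* The synthetic population's absolute life-course numbers depend on
  generator calibration choices (age profiles, persistence); only the
  qualitative structure — unimodal life-course, BMI dominance over the
  cholesterol ratio, decay of composition effects vs growth of update
  effects — is transferable.
* Backward elimination is used because it is the documented procedure; it
  inherits that procedure's known instabilities near the significance
  threshold.
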