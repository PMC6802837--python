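# flsim — microsimulation of the natural history of fatty liver

`flsim` models the life-course of fatty liver (hepatic steatosis by
ultrasonography) in adult Japanese men as a discrete-time, individual-level
state-transition process driven by lifestyle-related risk factors.  It is
aimed at epidemiological modellers who want a fully testable, reproducible
implementation of the published natural-history model: annual transition
probabilities for disease status, stochastic annual updates for the risk
factors, Monte Carlo life-course projection, the model-assessment exercises
(calibration, time-shift consistency, external comparison) and both
one-way sensitivity analyses.

## The model

Disease status is binary.  The annual transition probability is a
main-effects logistic in three binary predictors measured before the
transition — current status, BMI ≥ 25 kg/m², and LDL-C/HDL-C ≥ 2:

    logit P(FL_{t+1}) = β₀ + β_fl·FL_t + β_bmi·1[BMI_t ≥ 25] + β_ratio·1[LDL_t/HDL_t ≥ 2]

which induces the published 8-cell transition table (0.031 for the
all-normal cell up to 0.919 for the all-abnormal cell with prior disease).
Fitting this surface to the table's log-odds gives
β = (−3.445, 4.061, 0.893, 0.921).  BMI and the cholesterol ratio evolve by
fitted first-order autoregressions with age terms (the ratio on the log
scale); life-courses are projected by 10 replicate Monte Carlo runs and
summarized as mean prevalence ± 2 SD.  With covariates frozen each member
is a two-state chain whose long-run prevalence has the closed form
p01/(p01 + 1 − p11) — the simulator's analytic oracle.

Because the original cohort is not public, the package ships a first-class
synthetic-cohort generator (`flsim.cohort`) that reproduces the study
population's documented structure — skewed BMI with a 27% BMI≥25 fraction
at mean 23.3/SD 3.6, negatively correlated LDL/HDL, piecewise-linear age
profiles, 9%/6% annual enrollment/attrition, age-banded ultrasonography
missingness (0%/9.1%/95.5%) — with fatty-liver dynamics driven by a known
transition model, so parameter recovery and self-consistency can be tested
exactly.  See `docs/methods.md` for the full model description.

## Worked example

```python
import flsim

# a synthetic study population and the models fitted from it
pop = flsim.generate_population(flsim.study_population_config(seed=3, n_per_year=3000))
fl_model = flsim.fit_fl_transition(pop).validate()
updates = {v: flsim.fit_covariate_update(pop, v) for v in ("bmi", "ratio")}
print({k: round(v, 3) for k, v in fl_model.to_dict().items()})

# project the 30-39 cohort to ages 70-79
cohort2 = flsim.generate_population(flsim.cohort2_config(seed=4, n_per_year=2162))
traj = flsim.simulate_lifecourse(cohort2, fl_model, updates,
                                 flsim.SimulationConfig(n_runs=10, seed=2718))
f = traj.frame
peak = f["fl_mean"].idxmax()
print(f"{f['fl_mean'][0]:.3f} -> peak {f['fl_mean'][peak]:.3f} at mean age "
      f"{f['mean_age'][peak]:.0f} -> {f['fl_mean'].iloc[-1]:.3f} at 70-79")
```

prints (exactly, for these seeds):

```
{'beta0': -3.523, 'beta_fl': 4.103, 'beta_bmi': 0.912, 'beta_ratio': 1.005}
0.201 -> peak 0.288 at mean age 53 -> 0.251 at 70-79
```

The fitted coefficients recover the generating values (−3.445, 4.061,
0.893, 0.921) within sampling error at ~12k person-transitions, and the
projected life-course shows the characteristic unimodal shape: prevalence
rises from ~20% at 30-39, peaks near 29% while the cohort is in its 50s,
and falls to ~25% by 70-79.

## Analysis pipeline

The numbered drivers under `analysis/` run the full study at scale and
write their tables and figures under `results/`:

```bash
cd analysis
python 01_generate_cohort.py     # synthetic population -> results/panel.csv
python 02_fit_models.py          # transition + update models -> models.yaml
python 03_simulate_lifecourse.py # cohort-2 life-course + figure
python 04_validate_model.py      # V-1 calibration, V-2 time-shift (V-3 if configured)
python 05_sensitivity.py         # S-1 composition, S-2 update perturbations
```

At study scale this yields, e.g., 93% of calibration quantity-years inside
the ±2 SD band, all 10 time-shift band comparisons overlapping, and the
update-perturbation table (change in prevalence at the 50-59 band,
percentage points):

```
          -1.0%  -0.5%  +0.5%  +1.0%
bmi        -8.3   -5.2    6.4   12.4
ratio      -3.1   -1.5    1.3    2.5
```

i.e. annual BMI changes move the life-course several-fold more than equal
changes in the cholesterol ratio — the model's central comparative finding.
The same pipeline is available as a single command (`flsim run-study
--seed 0 --out outdir`) and as individual CLI subcommands
(`flsim generate / fit / simulate / validate / sensitivity`).

## Layout

    src/flsim/        library: cohort generation, risk flags, model fitting,
                      simulator, validation, sensitivity, I/O, CLI
    analysis/         numbered study drivers (thin, narrative)
    tests/            pytest suite (unit, property and acceptance tests)
    scripts/          acceptance script
    docs/methods.md   full methods note: model, assumptions, calibration,
                      numerical choices, limitations
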