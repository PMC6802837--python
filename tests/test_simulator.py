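"""Monte Carlo microsimulator: oracle equivalence, determinism, bands."""

import numpy as np
import pandas as pd
import pytest

import flsim
from flsim.models import CovariateUpdateModel, FLTransitionModel, stationary_prevalence
from flsim.simulate import (SimulationConfig, band_coverage, baseline_state,
                            simulate_lifecourse, simulate_year)


def state_in_cell(n: int, fl: float, bmi_flag: bool, ratio_flag: bool) -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": [f"m{i}" for i in range(n)],
        "age": 40.0,
        "fl": float(fl),
        "bmi": 30.0 if bmi_flag else 20.0,
        "ratio": 3.0 if ratio_flag else 1.5,
    })


class TestSimulateYear:
    def test_absorbing_cell_retains_status(self):
        """With the (1,1,1) cell forced to ~1, members with fatty liver and
        both risk flags never remit."""
        state = state_in_cell(500, fl=1, bmi_flag=True, ratio_flag=True)
        model = FLTransitionModel(beta0=0.0, beta_fl=40.0, beta_bmi=0.0, beta_ratio=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = simulate_year(state, model, {}, rng)
        assert (state["fl"] == 1.0).all()

    @pytest.mark.parametrize(
        "cell, p01, p11",
        [((False, False), 0.031, 0.649),    # all-normal cell pair
         ((True, True), 0.164, 0.919)],     # all-abnormal cell pair
    )
    def test_long_run_prevalence_matches_stationary_oracle(self, cell, p01, p11):
        """Frozen covariates reduce the simulator to a two-state chain; after
        200 years at n=2000 the prevalence sits on the closed-form fixed
        point (0.08115 / 0.66939) within 3 Monte Carlo standard errors."""
        bmi_flag, ratio_flag = cell
        state = state_in_cell(2000, fl=0, bmi_flag=bmi_flag, ratio_flag=ratio_flag)
        model = FLTransitionModel.published()
        rng = np.random.default_rng(42)
        for _ in range(200):
            state = simulate_year(state, model, {}, rng)
        target = stationary_prevalence(p01, p11)
        se = np.sqrt(target * (1 - target) / 2000)
        assert abs(state["fl"].mean() - target) <= 3 * se

    def test_perturbation_scales_predicted_update(self):
        """A noise-free rule predicting 25.0 with a 1% perturbation yields
        exactly 25.25."""
        state = state_in_cell(3, fl=0, bmi_flag=False, ratio_flag=False)
        update = {"bmi": CovariateUpdateModel("bmi", intercept=25.0, slope=0.0,
                                              resid_sd=0.0)}
        out = simulate_year(state, FLTransitionModel.published(), update,
                            np.random.default_rng(0), perturbation={"bmi": 1.01})
        assert np.allclose(out["bmi"], 25.25)

    def test_population_is_closed_and_ages_increment(self):
        state = state_in_cell(100, fl=0, bmi_flag=False, ratio_flag=False)
        out = simulate_year(state, FLTransitionModel.published(), {},
                            np.random.default_rng(1))
        assert len(out) == 100
        assert (out["age"] == 41.0).all()

    def test_unknown_perturbation_variable_rejected(self):
        state = state_in_cell(5, 0, False, False)
        with pytest.raises(ValueError, match="tg"):
            simulate_year(state, FLTransitionModel.published(), {},
                          np.random.default_rng(0), perturbation={"tg": 1.01})

    def test_perturbation_without_update_model_rejected(self):
        state = state_in_cell(5, 0, False, False)
        with pytest.raises(ValueError, match="update model"):
            simulate_year(state, FLTransitionModel.published(), {},
                          np.random.default_rng(0), perturbation={"bmi": 1.01})

    def test_covariates_stay_in_physiologic_bounds(self, fitted_models):
        fl_model, updates = fitted_models
        state = state_in_cell(300, fl=0, bmi_flag=True, ratio_flag=True)
        rng = np.random.default_rng(5)
        for _ in range(60):
            state = simulate_year(state, fl_model, updates, rng)
            assert state["bmi"].between(12, 60).all()
            assert state["ratio"].between(0, 10).all()


class TestLifecourse:
    def test_deterministic_given_seed(self, cohort2, fitted_models):
        fl_model, updates = fitted_models
        cfg = SimulationConfig(n_runs=3, horizon=10, seed=123)
        a = simulate_lifecourse(cohort2, fl_model, updates, cfg)
        b = simulate_lifecourse(cohort2, fl_model, updates, cfg)
        assert a.frame.equals(b.frame)

    def test_single_member_degenerate_no_incidence(self):
        state = state_in_cell(1, fl=0, bmi_flag=False, ratio_flag=False)
        model = FLTransitionModel(beta0=-50.0, beta_fl=1.0, beta_bmi=1.0,
                                  beta_ratio=1.0)
        traj = simulate_lifecourse(state, model, {},
                                   SimulationConfig(n_runs=5, horizon=8, seed=0))
        assert (traj.frame["fl_mean"] == 0.0).all()
        assert (traj.frame["fl_sd"] == 0.0).all()

    def test_sd_zero_for_single_run(self, cohort2, fitted_models):
        fl_model, updates = fitted_models
        traj = simulate_lifecourse(cohort2, fl_model, updates,
                                   SimulationConfig(n_runs=1, horizon=3, seed=1))
        for q in ("fl", "bmi", "ratio"):
            assert (traj.frame[f"{q}_sd"] == 0.0).all()

    def test_prevalences_are_proportions(self, cohort2, fitted_models):
        fl_model, updates = fitted_models
        traj = simulate_lifecourse(cohort2, fl_model, updates,
                                   SimulationConfig(n_runs=4, horizon=12, seed=2))
        for q in ("fl", "bmi", "ratio"):
            assert traj.frame[f"{q}_mean"].between(0, 1).all()
            assert (traj.frame[f"{q}_sd"] >= 0).all()

    def test_horizon_reaches_target_age_band(self, cohort2, fitted_models):
        fl_model, updates = fitted_models
        traj = simulate_lifecourse(cohort2, fl_model, updates,
                                   SimulationConfig(n_runs=2, seed=3, target_age=75))
        assert traj.frame["mean_age"].iloc[-1] == pytest.approx(75, abs=1)

    def test_baseline_requires_observed_status(self, study_population):
        df = study_population.df.copy()
        df.loc[df.index[:5], "fl"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            baseline_state(flsim.CohortPanel(df))

    def test_monotone_response_to_bmi_perturbation(self, cohort2, fitted_models):
        """Fatty-liver prevalence at the 50-59 band is nondecreasing in the
        BMI update multiplier (paired seeds; small Monte Carlo slack)."""
        fl_model, updates = fitted_models
        values = []
        for mult in (0.99, 0.995, 1.0, 1.005, 1.01):
            cfg = SimulationConfig(n_runs=5, seed=77, perturbation={"bmi": mult})
            traj = simulate_lifecourse(cohort2, fl_model, updates, cfg)
            values.append(traj.band_mean("fl", (50, 59)))
        for lo, hi in zip(values, values[1:]):
            assert hi >= lo - 0.01


class TestBandCoverage:
    def _traj(self, cohort2, fitted_models, seed=11):
        fl_model, updates = fitted_models
        return simulate_lifecourse(cohort2, fl_model, updates,
                                   SimulationConfig(n_runs=10, horizon=4, seed=seed))

    def test_observed_equal_to_means_is_covered(self, cohort2, fitted_models):
        traj = self._traj(cohort2, fitted_models)
        obs = dict(zip(traj.frame["year"], traj.frame["fl_mean"]))
        assert band_coverage(traj, obs).all()

    def test_three_sigma_excursion_flagged(self, cohort2, fitted_models):
        traj = self._traj(cohort2, fitted_models)
        f = traj.frame
        year = int(f.loc[f["fl_sd"] > 0, "year"].iloc[0])
        obs = {year: float(f.set_index("year").loc[year, "fl_mean"]
                           + 3 * f.set_index("year").loc[year, "fl_sd"])}
        assert not band_coverage(traj, obs).loc[year]

    def test_year_mismatch_rejected(self, cohort2, fitted_models):
        traj = self._traj(cohort2, fitted_models)
        with pytest.raises(ValueError, match="years"):
            band_coverage(traj, {999: 0.2})

    def test_self_generated_observations_are_mostly_covered(self, fitted_models):
        """Coverage oracle: when the observed series is one draw from the
        simulator's own model, the +/-2 SD band over 10 runs captures it in
        at least 80% of year-replicates."""
        fl_model, updates = fitted_models
        state = state_in_cell(300, fl=0, bmi_flag=False, ratio_flag=False)
        state["fl"] = (np.random.default_rng(1).random(300) < 0.2).astype(float)
        traj = simulate_lifecourse(state, fl_model, updates,
                                   SimulationConfig(n_runs=10, horizon=4, seed=500))
        covered = []
        for rep in range(200):
            one = simulate_lifecourse(state, fl_model, updates,
                                      SimulationConfig(n_runs=1, horizon=4,
                                                       seed=1000 + rep))
            obs = dict(zip(one.frame["year"][1:], one.frame["fl_mean"][1:]))
            covered.append(band_coverage(traj, obs).to_numpy())
        assert np.mean(covered) >= 0.80
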