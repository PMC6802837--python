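"""Transition-table reconstruction, stationary oracle, and model fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import flsim
from flsim.models import (PUBLISHED_TRANSITION_TABLE, FLTransitionModel,
                          build_table, fit_covariate_update, fit_fl_transition,
                          fit_imputation_model, fit_table_main_effects,
                          impute_missing_fl, stationary_prevalence,
                          transition_probability)

from conftest import make_panel, panel_from_flags


class TestTableReconstruction:
    def test_full_table_is_additive_on_logit_scale(self):
        """A main-effects fit to all 8 published cells reproduces every cell
        within 0.005: the printed table is internally consistent with an
        interaction-free logistic surface."""
        model = fit_table_main_effects(PUBLISHED_TRANSITION_TABLE)
        table = build_table(model)
        for cell, p in PUBLISHED_TRANSITION_TABLE.items():
            assert table[cell] == pytest.approx(p, abs=0.005)

    def test_recovered_coefficients(self):
        model = fit_table_main_effects(PUBLISHED_TRANSITION_TABLE)
        assert model.beta0 == pytest.approx(-3.445, abs=0.01)
        assert model.beta_fl == pytest.approx(4.061, abs=0.01)
        assert model.beta_bmi == pytest.approx(0.893, abs=0.01)
        assert model.beta_ratio == pytest.approx(0.921, abs=0.01)
        model.validate()

    @pytest.mark.parametrize("held_out", [(0, 1, 1), (0, 1, 0), (0, 0, 1)])
    def test_held_out_cell_prediction(self, held_out):
        """Each no-prior-status risk cell is predicted from the other seven
        cells to within 0.005 of its printed value."""
        cells = {k: v for k, v in PUBLISHED_TRANSITION_TABLE.items() if k != held_out}
        model = fit_table_main_effects(cells)
        predicted = transition_probability(model, *held_out)
        assert predicted == pytest.approx(PUBLISHED_TRANSITION_TABLE[held_out], abs=0.005)

    def test_exact_main_effects_table_recovered_exactly(self):
        truth = FLTransitionModel(beta0=-2.0, beta_fl=3.0, beta_bmi=0.5, beta_ratio=0.7)
        cells = build_table(truth).cells
        refit = fit_table_main_effects(cells)
        for name in ("beta0", "beta_fl", "beta_bmi", "beta_ratio"):
            assert getattr(refit, name) == pytest.approx(getattr(truth, name), abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        cells = {k: v for k, v in PUBLISHED_TRANSITION_TABLE.items() if k[0] == 0}
        with pytest.raises(ValueError, match="rank|span"):
            fit_table_main_effects(cells)
        with pytest.raises(ValueError, match=">= 4"):
            fit_table_main_effects({(0, 0, 0): 0.03, (1, 1, 1): 0.9})


class TestTransitionProbability:
    def test_published_corner_cells(self):
        model = FLTransitionModel.published()
        assert transition_probability(model, 0, 0, 0) == pytest.approx(0.031, abs=0.005)
        assert transition_probability(model, 1, 1, 1) == pytest.approx(0.919, abs=0.005)

    def test_zero_model_gives_half_everywhere(self):
        model = FLTransitionModel(0.0, 0.0, 0.0, 0.0)
        assert all(p == 0.5 for p in build_table(model).cells.values())

    def test_saturation_in_prior_status(self):
        model = FLTransitionModel(beta0=-3.4, beta_fl=15.0, beta_bmi=0.9, beta_ratio=0.9)
        table = build_table(model)
        for cell, p in table.cells.items():
            if cell[0] == 1:
                assert p > 0.999

    def test_published_table_is_monotone(self):
        assert build_table(FLTransitionModel.published()).is_monotone()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(beta0=st.floats(-5, 1), b1=st.floats(0.01, 5),
           b2=st.floats(0.01, 5), b3=st.floats(0.01, 5))
    def test_any_risk_increasing_model_yields_monotone_table(self, beta0, b1, b2, b3):
        table = build_table(FLTransitionModel(beta0, b1, b2, b3))
        assert table.is_monotone()


class TestStationaryPrevalence:
    @pytest.mark.parametrize(
        "p01, p11, expected",
        [(0.031, 0.649, 0.031 / (0.031 + 0.351)),   # all-normal cell: 0.08115
         (0.164, 0.919, 0.164 / (0.164 + 0.081)),   # all-abnormal, no prior: 0.66939
         (0.5, 0.5, 0.5)],
    )
    def test_closed_form(self, p01, p11, expected):
        assert stationary_prevalence(p01, p11) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_absorbing_chain_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stationary_prevalence(0.0, 1.0)

    @pytest.mark.parametrize("p01, p11", [(0.031, 0.649), (0.164, 0.919)])
    def test_matches_chain_simulation(self, p01, p11):
        """Independent oracle: many parallel two-state chains, long past
        mixing, land on the closed-form fixed point."""
        rng = np.random.default_rng(0)
        n, steps = 5000, 300
        state = np.zeros(n, dtype=bool)
        for _ in range(steps):
            p = np.where(state, p11, p01)
            state = rng.random(n) < p
        target = stationary_prevalence(p01, p11)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(state.mean() - target) <= 3 * se

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p01=st.floats(1e-3, 1.0), p11=st.floats(0.0, 1 - 1e-3))
    def test_is_a_fixed_point(self, p01, p11):
        pi = stationary_prevalence(p01, p11)
        assert 0.0 <= pi <= 1.0
        assert (1 - pi) * p01 + pi * p11 == pytest.approx(pi, abs=1e-12)


class TestTransitionFit:
    def test_recovers_generating_coefficients(self, study_population):
        """On a panel with >10k person-transitions generated by the known
        model, every coefficient comes back within 0.15 of truth."""
        truth = FLTransitionModel.published()
        fit = fit_fl_transition(study_population)
        assert fit.fit_info["n_transitions"] >= 10_000
        assert set(fit.fit_info["survivors"]) == {"bmi", "ratio"}
        for name in ("beta0", "beta_fl", "beta_bmi", "beta_ratio"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), abs=0.15)

    def test_null_candidate_eliminated(self):
        """A flag with zero true effect is dropped at alpha=0.05 in at least
        90% of replicates (backward elimination controls type-I inclusion)."""
        truth = FLTransitionModel.published()
        rng = np.random.default_rng(12345)
        kept = 0
        n_rep, n = 200, 400
        for _ in range(n_rep):
            bmi = rng.random(n) < 0.3
            ratio = rng.random(n) < 0.5
            tg = rng.random(n) < 0.3            # no effect on transition
            fl_t = rng.random(n) < 0.25
            p = transition_probability(truth, fl_t.astype(float),
                                       bmi.astype(float), ratio.astype(float))
            fl_t1 = rng.random(n) < p
            panel = panel_from_flags(bmi, ratio, fl_t, fl_t1, tg_flag=tg)
            try:
                fit = fit_fl_transition(panel, candidate_flags=("bmi", "ratio", "tg"))
            except ValueError:
                continue  # rare separation at n=400
            if "tg" in fit.fit_info["survivors"]:
                kept += 1
        assert kept / n_rep <= 0.10

    def test_near_deterministic_persistence_dominates(self):
        rng = np.random.default_rng(7)
        n = 2000
        bmi = rng.random(n) < 0.3
        ratio = rng.random(n) < 0.5
        fl_t = rng.random(n) < 0.5
        flip = rng.random(n) < 0.02
        fl_t1 = np.where(flip, ~fl_t, fl_t)
        fit = fit_fl_transition(panel_from_flags(bmi, ratio, fl_t, fl_t1))
        assert fit.beta_fl > 3.0
        assert fit.fit_info["survivors"] == []   # both flags eliminated
        assert fit.beta_bmi == 0.0 and fit.beta_ratio == 0.0

    def test_complete_separation_rejected_with_diagnostic(self):
        n = 200
        fl_t = np.arange(n) % 2 == 0
        panel = panel_from_flags(np.zeros(n, bool), np.ones(n, bool), fl_t, fl_t)
        with pytest.raises(ValueError, match="separation|failed|degenerate"):
            fit_fl_transition(panel)

    def test_too_few_transitions_rejected(self):
        n = 20
        panel = panel_from_flags(np.zeros(n, bool), np.zeros(n, bool),
                                 np.zeros(n), np.zeros(n))
        with pytest.raises(ValueError, match="50"):
            fit_fl_transition(panel)


def _pairs_panel(v_t: np.ndarray, v_t1: np.ndarray, ages: np.ndarray) -> flsim.CohortPanel:
    n = len(v_t)
    frames = []
    for wave, v in ((0, v_t), (1, v_t1)):
        frames.append(pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)], "year": 2012 + wave,
            "age": ages + wave, "fl": 0.0,
            "bmi": v, "ldl": 120.0, "hdl": 55.0, "tg": 110.0,
            "sbp": 120.0, "hba1c": 5.3,
            "smoker": False, "drinker": False, "exerciser": False,
            "shiftworker": False,
        }))
    return flsim.CohortPanel(pd.concat(frames, ignore_index=True))


class TestCovariateUpdateFit:
    def test_recovers_slope_and_residual_sd(self):
        rng = np.random.default_rng(21)
        n = 10_000
        ages = rng.integers(30, 60, n)
        v_t = rng.normal(24.0, 3.5, n)
        v_t1 = 1.2 + 0.95 * v_t + rng.normal(0.0, 0.8, n)
        model = fit_covariate_update(_pairs_panel(v_t, v_t1, ages), "bmi")
        assert model.variable == "bmi"
        assert model.slope == pytest.approx(0.95, abs=0.02)
        assert model.resid_sd == pytest.approx(0.8, abs=0.05)
        assert model.n_pairs == n

    def test_identity_dynamics(self):
        rng = np.random.default_rng(22)
        v = rng.normal(24.0, 3.0, 500)
        model = fit_covariate_update(_pairs_panel(v, v, rng.integers(30, 60, 500)), "bmi")
        assert model.slope == pytest.approx(1.0, abs=1e-8)
        assert model.resid_sd == pytest.approx(0.0, abs=1e-8)
        assert model.predict(25.0, 40) == pytest.approx(25.0, abs=1e-6)

    def test_permuted_pairs_have_no_slope(self):
        rng = np.random.default_rng(23)
        n = 5000
        v_t = rng.normal(24.0, 3.5, n)
        v_t1 = 1.2 + 0.95 * v_t + rng.normal(0.0, 0.8, n)
        v_t1 = rng.permutation(v_t1)            # break the pairing
        model = fit_covariate_update(_pairs_panel(v_t, v_t1, rng.integers(30, 60, n)), "bmi")
        se = np.std(v_t1) / (np.std(v_t) * np.sqrt(n))
        assert abs(model.slope) <= 3 * se

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(24)
        v = rng.normal(24, 3, 10)
        with pytest.raises(ValueError, match="50"):
            fit_covariate_update(_pairs_panel(v, v, np.full(10, 40)), "bmi")

    def test_ratio_is_fitted_from_ldl_over_hdl(self, study_population):
        model = fit_covariate_update(study_population, "ratio")
        assert 0.5 < model.slope < 1.0
        assert model.resid_sd > 0


class TestImputation:
    def test_zero_probability_model_imputes_absent(self, study_population):
        df = study_population.df.copy()
        df.loc[df.index[:500], "fl"] = np.nan
        panel = flsim.CohortPanel(df)
        model = flsim.ImputationModel(terms=("bmi", "ratio"), intercept=-50.0,
                                      coefs=(0.0, 0.0))
        out = impute_missing_fl(panel, model, seed=0)
        assert (out.df.loc[df.index[:500], "fl"] == 0.0).all()

    def test_observed_statuses_never_altered_and_deterministic(self, study_population):
        df = study_population.df.copy()
        blank = df.sample(n=2000, random_state=5).index
        panel = flsim.CohortPanel(df.assign(fl=df["fl"].mask(df.index.isin(blank))))
        model = fit_imputation_model(study_population)
        a = impute_missing_fl(panel, model, seed=9)
        b = impute_missing_fl(panel, model, seed=9)
        assert a.df.equals(b.df)
        untouched = ~panel.df["fl"].isna()
        assert a.df.loc[untouched, "fl"].equals(panel.df.loc[untouched, "fl"])

    def test_imputed_prevalence_matches_observed(self, study_population):
        """Blanking a random subset (same covariate distribution as the rest)
        and imputing reproduces the observed prevalence within 3 binomial SEs."""
        df = study_population.df.copy()
        rng = np.random.default_rng(11)
        blank = df.sample(frac=0.3, random_state=11).index
        panel = flsim.CohortPanel(df.assign(fl=df["fl"].mask(df.index.isin(blank))))
        model = fit_imputation_model(panel, age_range=(20, 99))
        out = impute_missing_fl(panel, model, seed=13)
        p_obs = panel.df["fl"].dropna().mean()
        imputed = out.df.loc[blank, "fl"]
        se = np.sqrt(p_obs * (1 - p_obs) / len(blank))
        assert abs(imputed.mean() - p_obs) <= 3 * se

    def test_missing_covariate_rejected(self, study_population):
        model = flsim.ImputationModel(terms=("nonexistent",), intercept=0.0, coefs=(1.0,))
        df = study_population.df.copy()
        df.loc[df.index[:10], "fl"] = np.nan
        with pytest.raises(ValueError, match="nonexistent"):
            impute_missing_fl(flsim.CohortPanel(df), model, seed=0)
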