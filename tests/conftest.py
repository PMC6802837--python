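"""Shared fixtures: one synthetic study population and models fitted from it.

Session-scoped because generation and fitting are reused by many tests; all
seeds are fixed so the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import flsim

STUDY_SEED = 3
COHORT2_SEED = 4


@pytest.fixture(scope="session")
def study_population() -> flsim.CohortPanel:
    """Synthetic analogue of the examined population (fully observed)."""
    cfg = flsim.study_population_config(seed=STUDY_SEED, n_per_year=3000, years=5)
    return flsim.generate_population(cfg)


@pytest.fixture(scope="session")
def fitted_models(study_population):
    """Transition and annual-update models fitted from the fixture panel."""
    fl_model = flsim.fit_fl_transition(study_population).validate()
    updates = {v: flsim.fit_covariate_update(study_population, v)
               for v in ("bmi", "ratio")}
    return fl_model, updates


@pytest.fixture(scope="session")
def cohort2(study_population) -> flsim.CohortPanel:
    """Projection cohort calibrated to the youngest age band (30-39)."""
    cfg = flsim.cohort2_config(seed=COHORT2_SEED, n_per_year=2162)
    return flsim.generate_population(cfg)


def make_panel(records: list[dict]) -> flsim.CohortPanel:
    """Panel from explicit person-year dicts; unspecified fields defaulted."""
    defaults = {"fl": 0.0, "bmi": 23.0, "ldl": 120.0, "hdl": 55.0, "tg": 110.0,
                "sbp": 120.0, "hba1c": 5.3, "smoker": False, "drinker": False,
                "exerciser": False, "shiftworker": False}
    rows = [{**defaults, **r} for r in records]
    return flsim.CohortPanel(pd.DataFrame(rows))


def panel_from_flags(bmi_flag, ratio_flag, fl_t, fl_t1, tg_flag=None,
                     first_year: int = 2012) -> flsim.CohortPanel:
    """Two-wave panel whose dichotomized states equal the given flag arrays.

    Continuous values are placed well inside the normal/abnormal regions so
    the flag layer is unambiguous; wave-2 covariates repeat wave 1 (only the
    wave-1 values enter a transition fit).
    """
    bmi_flag = np.asarray(bmi_flag, dtype=bool)
    n = len(bmi_flag)
    ratio_flag = np.asarray(ratio_flag, dtype=bool)
    tg_flag = np.zeros(n, dtype=bool) if tg_flag is None else np.asarray(tg_flag, bool)
    bmi = np.where(bmi_flag, 28.0, 22.0)
    ldl = np.full(n, 120.0)
    hdl = np.where(ratio_flag, 50.0, 70.0)  # ratio 2.4 vs 1.71
    tg = np.where(tg_flag, 200.0, 100.0)
    frames = []
    for wave, fl in ((0, np.asarray(fl_t, float)), (1, np.asarray(fl_t1, float))):
        frames.append(pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "year": first_year + wave,
            "age": 40 + wave,
            "fl": fl,
            "bmi": bmi, "ldl": ldl, "hdl": hdl, "tg": tg,
            "sbp": 120.0, "hba1c": 5.3,
            "smoker": False, "drinker": False, "exerciser": False,
            "shiftworker": False,
        }))
    return flsim.CohortPanel(pd.concat(frames, ignore_index=True))
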