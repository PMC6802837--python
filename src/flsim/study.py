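"""End-to-end study driver: generate -> impute -> fit -> simulate -> validate
-> sensitivity, with per-stage logging and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import cohort as _cohort
from . import models as _models
from . import sensitivity as _sens
from . import validate as _val
from .cohort import (CohortPanel, apply_missingness, cohort2_config,
                     generate_population, select_cohort, study_population_config)
from .io import write_panel
from .models import (build_table, fit_covariate_update, fit_fl_transition,
                     fit_imputation_model, impute_missing_fl, models_to_yaml)
from .simulate import SimulationConfig, simulate_lifecourse

__all__ = ["default_config", "run_study"]

log = logging.getLogger("flsim")

REQUIRED_SECTIONS = ("synthetic", "fitting", "simulation", "validation", "sensitivity")


def default_config() -> dict:
    """Study-scale configuration (the scale the analyses are reported at)."""
    return {
        "synthetic": {
            "n_per_year": 2000,
            "years": 5,
            "apply_missingness": True,
        },
        "fitting": {
            "candidate_flags": ["bmi", "ratio", "tg", "sbp", "hba1c",
                                 "smoker", "drinker", "exerciser", "shiftworker"],
            "alpha": 0.05,
        },
        "simulation": {
            "n_runs": 10,
            "target_age": 75,
        },
        "validation": {
            "calibration_age_range": [20, 69],
            "timeshift_bands": [[30, 39], [40, 49], [50, 59]],
            # external prevalence tables are user-supplied; empty disables V-3
            "external": {},
        },
        "sensitivity": {
            "axes": ["bmi", "ldl", "hdl", "ratio", "tg", "sbp", "hba1c",
                      "smoker", "drinker", "exerciser", "shiftworker"],
            "factors": [-0.4, -0.2, 0.0, 0.2, 0.4],
            "deltas": [-0.01, -0.005, 0.0, 0.005, 0.01],
        },
    }


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(config: Mapping | str | Path, outdir, seed: int = 0) -> dict:
    """Execute the full pipeline and write all artifacts to ``outdir``.

    ``config`` is a mapping or a YAML path with sections ``synthetic``,
    ``fitting``, ``simulation``, ``validation`` and ``sensitivity``.  Any
    stage failure aborts with the stage name.  Returns the manifest, which
    records the seed, a config hash and per-stage wall times.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for section in REQUIRED_SECTIONS:
        if section not in config:
            raise ValueError(f"config is missing the {section!r} section")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "config_hash": _config_hash(config),
                      "stages": {}, "outputs": []}
    rng_seeds = np.random.default_rng(seed).integers(2**31, size=8)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = {"seconds": round(dt, 3), "ok": exc is None}
                if exc is not None:
                    log.error("stage %s: failed after %.1fs: %s", name, dt, exc)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.1fs", name, dt)
                return False
        return _Timer()

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    # -- generate ----------------------------------------------------------
    with stage("generate"):
        syn = config["synthetic"]
        gen_cfg = study_population_config(
            seed=int(rng_seeds[0]),
            n_per_year=int(syn.get("n_per_year", 2000)),
            years=int(syn.get("years", 5)),
        )
        population = generate_population(gen_cfg)
        if syn.get("apply_missingness", True):
            population = apply_missingness(population, gen_cfg.missingness,
                                           seed=int(rng_seeds[1]))
        emit("panel.csv", lambda p: write_panel(population, p))

    # -- fit ---------------------------------------------------------------
    # transitions use observed statuses only; imputed draws carry no
    # year-to-year dependence and would attenuate the persistence term
    with stage("fit"):
        fit_cfg = config["fitting"]
        fl_model = fit_fl_transition(
            population,
            candidate_flags=tuple(fit_cfg.get("candidate_flags", ["bmi", "ratio"])),
            alpha=float(fit_cfg.get("alpha", 0.05)),
        )
        update_models = {v: fit_covariate_update(population, v) for v in ("bmi", "ratio")}

    # -- impute (completes simulation baselines in the youngest bands) -----
    with stage("impute"):
        imput = fit_imputation_model(population)
        imputed = impute_missing_fl(population, imput, seed=int(rng_seeds[2]))
        emit("models.yaml", lambda p: models_to_yaml(p, fl_model, update_models, imput))
        emit("transition_table.csv",
             lambda p: build_table(fl_model).to_frame().to_csv(p, index=False))

    # -- simulate ----------------------------------------------------------
    with stage("simulate"):
        sim = config["simulation"]
        sim_cfg = SimulationConfig(n_runs=int(sim.get("n_runs", 10)),
                                   target_age=int(sim.get("target_age", 75)),
                                   seed=int(rng_seeds[3]))
        cohort2 = select_cohort(imputed, (30, 39))
        traj = simulate_lifecourse(cohort2, fl_model, update_models, sim_cfg)
        emit("trajectory_cohort2.csv", traj.to_csv)
        emit("fig_lifecourse.png", lambda p: traj.plot(p))

    # -- validate ----------------------------------------------------------
    with stage("validate"):
        val = config["validation"]
        cal_range = tuple(val.get("calibration_age_range", (20, 69)))
        cohort1 = select_cohort(population, cal_range, complete_cases_only=True)
        cal = _val.calibrate_v1(cohort1, fl_model, update_models, sim_cfg)
        emit("calibration_v1.csv", lambda p: cal.frame.to_csv(p, index=False))
        emit("fig_calibration.png", lambda p: cal.traj.plot(
            p, observed={int(r["year"]): r["fl"]
                         for _, r in _val.observed_prevalences(cohort1).iterrows()}))
        bands = [tuple(b) for b in val.get("timeshift_bands",
                                           [(30, 39), (40, 49), (50, 59)])]
        cohorts = [select_cohort(imputed, b) for b in bands]
        ts = _val.time_shift_v2(cohorts, fl_model, update_models, sim_cfg,
                                labels=[f"{b[0]}-{b[1]}" for b in bands])
        emit("timeshift_v2.csv", lambda p: ts.frame.to_csv(p, index=False))
        external = {tuple(int(x) for x in str(k).split("-")): v
                    for k, v in (val.get("external") or {}).items()}
        if external:
            ext = _val.external_compare_v3(traj, external)
            emit("external_v3.csv", lambda p: ext.frame.to_csv(p, index=False))

    # -- sensitivity -------------------------------------------------------
    with stage("sensitivity"):
        sens = config["sensitivity"]
        init = _sens.sweep_initial(cohort2, fl_model, update_models, sim_cfg,
                                   axes=tuple(sens.get("axes", ("bmi", "ratio"))),
                                   factors=tuple(sens.get("factors",
                                                          (-0.4, -0.2, 0.0, 0.2, 0.4))))
        emit("sensitivity_initial.csv", lambda p: init.to_csv(p, index=False))
        upd = _sens.sweep_updates(cohort2, fl_model, update_models, sim_cfg,
                                  deltas=tuple(sens.get("deltas",
                                                        (-0.01, -0.005, 0.0, 0.005, 0.01))))
        emit("sensitivity_updates.csv", lambda p: upd.to_csv(p, index=False))
        emit("updates_table.csv", lambda p: _sens.updates_table(upd).to_csv(p))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
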