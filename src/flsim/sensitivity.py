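"""One-way sensitivity analysis of the fatty-liver life-course.

Two exercises, mirroring how state-transition models are usually probed:

* S-1 initial composition: resample the projection cohort so that one risk
  category's baseline prevalence moves by +/-20% or +/-40% (relative), then
  re-project and record the change in fatty-liver prevalence.
* S-2 annual updates: multiply one covariate's predicted annual update by
  1 +/- 0.5% or 1%, compounding over the horizon, and record the change.

Both use paired seeds (identical random-number streams in the baseline and
perturbed arms), so the change at zero variation is exactly 0 and Monte
Carlo noise largely cancels from the contrasts.  Changes are reported in
percentage points; the reference band for the headline change is ages
50-59, where the life-course peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortPanel
from .models import CovariateUpdateModel, FLTransitionModel
from .risk import FLAG_NAMES, LIFESTYLE_FIELDS, RiskThresholds, flag_frame
from .simulate import SimulationConfig, TrajectoryResult, simulate_lifecourse

__all__ = [
    "SensitivityResult",
    "vary_initial",
    "sweep_initial",
    "sweep_updates",
    "REFERENCE_BAND",
]

#: age band at which the headline prevalence change is read off
REFERENCE_BAND = (50, 59)

VALID_AXES = tuple(FLAG_NAMES) + tuple(LIFESTYLE_FIELDS)


@dataclass
class SensitivityResult:
    """Prevalence response of one axis at one variation level.

    ``change_ref_pp`` is the fatty-liver prevalence change (percentage
    points) at the 50-59 reference band; ``max_abs_change_pp`` the maximum
    absolute per-year change over the projection; ``change_year5_pp`` and
    ``change_final_pp`` support the decay/growth contrast between early and
    late projection years.
    """

    axis: str
    kind: str  # "initial" or "update"
    level: float
    change_ref_pp: float
    max_abs_change_pp: float
    change_year5_pp: float
    change_final_pp: float
    baseline_prevalence: float | None = None
    varied_prevalence: float | None = None


def _axis_flags(df: pd.DataFrame, axis: str, thresholds: RiskThresholds) -> np.ndarray:
    if axis in LIFESTYLE_FIELDS:
        return df[axis].astype(bool).to_numpy()
    return flag_frame(df, thresholds)[axis].to_numpy()


def vary_initial(
    cohort: CohortPanel,
    flag: str,
    factor: float,
    seed: int = 0,
    thresholds: RiskThresholds | None = None,
) -> CohortPanel:
    """Resample the cohort so one category's baseline prevalence changes.

    Stratified resampling with replacement by flag status: the varied
    cohort has the same size, with ``round((1 + factor) * p * n)`` members
    drawn from the flagged stratum and the rest from the unflagged one.
    Other marginals are disturbed only through the resampling.  With
    ``factor == 0`` the input cohort is returned unchanged.
    """
    thresholds = thresholds or RiskThresholds()
    if flag not in VALID_AXES:
        raise ValueError(f"unknown axis {flag!r}; valid: {VALID_AXES}")
    if not -0.9 <= factor <= 0.9:
        raise ValueError(f"variation factor {factor} outside [-0.9, 0.9]")
    if factor == 0.0:
        return cohort
    base = cohort.baseline()
    flags = _axis_flags(base, flag, thresholds)
    p0 = float(flags.mean())
    target = (1.0 + factor) * p0
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"target prevalence {target:.3f} for {flag!r} outside (0, 1)"
        )
    n = len(base)
    n_flagged = int(round(target * n))
    pos = np.flatnonzero(flags)
    neg = np.flatnonzero(~flags)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"stratum for {flag!r} is empty; cannot resample")
    rng = np.random.default_rng(seed)
    take = np.concatenate([
        rng.choice(pos, size=n_flagged, replace=True),
        rng.choice(neg, size=n - n_flagged, replace=True),
    ])
    out = base.iloc[take].copy().reset_index(drop=True)
    out["person_id"] = [f"r{i:06d}" for i in range(n)]
    meta = dict(cohort.meta)
    meta["varied"] = {"axis": flag, "factor": factor, "from": p0,
                      "to": n_flagged / n, "seed": seed}
    return CohortPanel(out, meta=meta)


def _diff_metrics(base: TrajectoryResult, varied: TrajectoryResult) -> dict:
    b, v = base.frame, varied.frame
    n = min(len(b), len(v))
    diff = (v["fl_mean"].to_numpy()[:n] - b["fl_mean"].to_numpy()[:n]) * 100.0
    ref = (varied.band_mean("fl", REFERENCE_BAND) - base.band_mean("fl", REFERENCE_BAND)) * 100.0
    y5 = int(min(5, n - 1))
    return {
        "change_ref_pp": float(ref),
        "max_abs_change_pp": float(np.max(np.abs(diff))),
        "change_year5_pp": float(diff[y5]),
        "change_final_pp": float(diff[n - 1]),
    }


def sweep_initial(
    cohort: CohortPanel,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    config: SimulationConfig,
    axes: Sequence[str] = ("bmi", "ldl", "hdl", "ratio", "tg", "sbp", "hba1c",
                           "smoker", "drinker", "exerciser", "shiftworker"),
    factors: Sequence[float] = (-0.4, -0.2, 0.0, 0.2, 0.4),
) -> pd.DataFrame:
    """S-1: vary each axis's baseline prevalence and re-project (paired seeds).

    Returns one row per axis x factor with the prevalence changes relative
    to the unvaried baseline run.
    """
    unknown = set(axes) - set(VALID_AXES)
    if unknown:
        raise ValueError(f"unknown axes: {sorted(unknown)}")
    base_traj = simulate_lifecourse(cohort, fl_model, update_models, config)
    thresholds = config.thresholds
    base0 = cohort.baseline()
    rows = []
    for i, axis in enumerate(axes):
        p0 = float(_axis_flags(base0, axis, thresholds).mean())
        for j, factor in enumerate(factors):
            if factor == 0.0:
                res = SensitivityResult(axis=axis, kind="initial", level=0.0,
                                        change_ref_pp=0.0, max_abs_change_pp=0.0,
                                        change_year5_pp=0.0, change_final_pp=0.0,
                                        baseline_prevalence=p0, varied_prevalence=p0)
                rows.append(res)
                continue
            varied = vary_initial(cohort, axis, factor,
                                  seed=int(np.random.default_rng(
                                      [config.seed, 1000 + i, j]).integers(2**31)),
                                  thresholds=thresholds)
            traj = simulate_lifecourse(varied, fl_model, update_models, config)
            res = SensitivityResult(
                axis=axis, kind="initial", level=factor,
                baseline_prevalence=p0,
                varied_prevalence=varied.meta["varied"]["to"],
                **_diff_metrics(base_traj, traj),
            )
            rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])


def sweep_updates(
    cohort: CohortPanel,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    config: SimulationConfig,
    variables: Sequence[str] = ("bmi", "ratio"),
    deltas: Sequence[float] = (-0.01, -0.005, 0.0, 0.005, 0.01),
) -> pd.DataFrame:
    """S-2: perturb annual covariate updates and re-project (paired seeds).

    Each variable's predicted annual update is multiplied by ``1 + delta``;
    the perturbation compounds over the horizon.  Deltas of magnitude 0.1
    or more are outside the studied regime and rejected.
    """
    for v in variables:
        if v not in update_models:
            raise ValueError(f"no update model for variable {v!r}")
    for d in deltas:
        if abs(d) >= 0.1:
            raise ValueError(f"update perturbation {d} outside the studied regime (|delta| < 0.1)")
    base_traj = simulate_lifecourse(cohort, fl_model, update_models, config)
    rows = []
    for var in variables:
        for d in deltas:
            if d == 0.0:
                rows.append(SensitivityResult(axis=var, kind="update", level=0.0,
                                              change_ref_pp=0.0, max_abs_change_pp=0.0,
                                              change_year5_pp=0.0, change_final_pp=0.0))
                continue
            cfg = SimulationConfig(
                n_runs=config.n_runs, horizon=config.horizon,
                target_age=config.target_age, seed=config.seed,
                perturbation={**dict(config.perturbation), var: 1.0 + d},
                thresholds=config.thresholds,
            )
            traj = simulate_lifecourse(cohort, fl_model, update_models, cfg)
            rows.append(SensitivityResult(axis=var, kind="update", level=d,
                                          **_diff_metrics(base_traj, traj)))
    return pd.DataFrame([r.__dict__ for r in rows])


def updates_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot S-2 results into the published layout: one row per variable,
    variation columns -1.0%, -0.5%, +0.5%, +1.0% (changes in percentage
    points at the 50-59 reference band)."""
    f = results[results["kind"] == "update"]
    f = f[f["level"] != 0.0]
    pivot = f.pivot(index="axis", columns="level", values="change_ref_pp")
    pivot.columns = [f"{100 * c:+.1f}%" for c in pivot.columns]
    pivot.index.name = "variable"
    return pivot
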