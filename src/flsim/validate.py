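"""Model-assessment exercises: calibration, time-shift consistency, external data.

Three checks mirror standard practice for population disease-simulation
models:

* V-1 calibration: simulate the fitting cohort over its own observation
  years and ask whether the observed prevalences (fatty liver, BMI>=25,
  LDL/HDL>=2) fall inside the +/-2 SD Monte Carlo band each year.
* V-2 internal consistency: project cohorts with different baseline ages to
  the 70-79 band and compare their trajectories on a common age axis; in
  each shared decade band the means should agree within
  2*(SD_A + SD_B) — a conservative formalization of "the trajectories
  almost overlapped".
* V-3 external consistency: compare band means against user-supplied
  prevalence tables from other populations (configured, never bundled).

All reports are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CovariateUpdateModel, FLTransitionModel
from .risk import RiskThresholds, flag_frame
from .simulate import SimulationConfig, TrajectoryResult, simulate_lifecourse

__all__ = [
    "CalibrationReport",
    "TimeShiftReport",
    "ExternalReport",
    "observed_prevalences",
    "calibrate_v1",
    "time_shift_v2",
    "external_compare_v3",
    "AGE_BANDS",
]

#: decade bands used to align trajectories on age
AGE_BANDS = ((30, 39), (40, 49), (50, 59), (60, 69), (70, 79))


@dataclass
class CalibrationReport:
    """Year-by-year band coverage of the fitting cohort (V-1)."""

    frame: pd.DataFrame  # columns: quantity, year, observed, mean, sd, covered
    traj: TrajectoryResult

    def coverage_fraction(self, quantity: str | None = None) -> float:
        f = self.frame if quantity is None else self.frame[self.frame["quantity"] == quantity]
        return float(f["covered"].mean())

    def all_covered(self) -> bool:
        return bool(self.frame["covered"].all())


@dataclass
class TimeShiftReport:
    """Pairwise age-band overlap of cohort trajectories (V-2)."""

    frame: pd.DataFrame  # columns: quantity, band, cohort_a, cohort_b, mean_a, mean_b, sd_a, sd_b, overlap
    trajectories: dict

    def all_overlap(self, quantity: str = "fl") -> bool:
        f = self.frame[self.frame["quantity"] == quantity]
        return bool(f["overlap"].all())


@dataclass
class ExternalReport:
    """Band-level comparison against externally observed prevalences (V-3)."""

    frame: pd.DataFrame  # columns: band, sim_mean, ext_min, ext_max, difference, inside, comparable


def observed_prevalences(panel, thresholds: RiskThresholds | None = None) -> pd.DataFrame:
    """Observed per-wave prevalence of the three tracked quantities.

    Fatty-liver prevalence uses observed statuses only; flag prevalences
    use rows with complete continuous fields.
    """
    thresholds = thresholds or RiskThresholds()
    df = getattr(panel, "df", panel)
    rows = []
    for i, (year, wave) in enumerate(sorted(df.groupby("year"))):
        flags = flag_frame(wave.dropna(subset=["bmi", "ldl", "hdl", "tg", "sbp", "hba1c"]),
                           thresholds)
        rows.append({
            "year": i,
            "calendar_year": year,
            "fl": float(wave["fl"].dropna().mean()),
            "bmi": float(flags["bmi"].mean()),
            "ratio": float(flags["ratio"].mean()),
        })
    return pd.DataFrame(rows)


def calibrate_v1(
    panel,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    config: SimulationConfig,
) -> CalibrationReport:
    """Simulate the fitting cohort across its observed years (V-1).

    The panel must contain at least two observed waves; projection starts
    from wave 1 and runs for (n_waves - 1) years.  The report records, per
    quantity and year, the observed prevalence, the simulated mean and SD,
    and whether |observed - mean| <= 2 SD.
    """
    df = getattr(panel, "df", panel)
    n_waves = df["year"].nunique()
    if n_waves < 2:
        raise ValueError(f"calibration needs >= 2 observed waves, got {n_waves}")
    obs = observed_prevalences(panel, config.thresholds)
    cfg = SimulationConfig(
        n_runs=config.n_runs, horizon=n_waves - 1, seed=config.seed,
        perturbation=config.perturbation, thresholds=config.thresholds,
    )
    traj = simulate_lifecourse(panel, fl_model, update_models, cfg)
    f = traj.frame.set_index("year")
    rows = []
    for q in ("fl", "bmi", "ratio"):
        for _, r in obs.iterrows():
            y = int(r["year"])
            mean, sd = float(f.loc[y, f"{q}_mean"]), float(f.loc[y, f"{q}_sd"])
            rows.append({
                "quantity": q, "year": y, "observed": float(r[q]),
                "mean": mean, "sd": sd,
                "covered": bool(abs(r[q] - mean) <= 2.0 * sd),
            })
    return CalibrationReport(frame=pd.DataFrame(rows), traj=traj)


def _band_stats(traj: TrajectoryResult, quantity: str) -> dict[tuple[int, int], tuple[float, float]]:
    out = {}
    for band in AGE_BANDS:
        m = traj.band_mean(quantity, band)
        if not np.isnan(m):
            out[band] = (m, traj.band_sd(quantity, band))
    return out


def time_shift_v2(
    cohorts: Sequence,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    config: SimulationConfig,
    labels: Sequence[str] | None = None,
) -> TimeShiftReport:
    """Project cohorts with different baseline ages and align on age (V-2).

    Each cohort is projected until its members reach the 70-79 band; for
    every pair of cohorts and every decade band both trajectories visit,
    overlap requires |mean_A - mean_B| <= 2*(SD_A + SD_B).
    """
    if len(cohorts) < 2:
        raise ValueError("time-shift comparison needs >= 2 cohorts")
    labels = list(labels or [f"cohort_{i}" for i in range(len(cohorts))])
    trajs = {}
    for i, (label, cohort) in enumerate(zip(labels, cohorts)):
        cfg = SimulationConfig(n_runs=config.n_runs, horizon=config.horizon,
                               target_age=config.target_age, seed=config.seed + i,
                               perturbation=config.perturbation,
                               thresholds=config.thresholds)
        trajs[label] = simulate_lifecourse(cohort, fl_model, update_models, cfg)
    rows = []
    for q in ("fl", "bmi", "ratio"):
        stats = {label: _band_stats(t, q) for label, t in trajs.items()}
        for a, b in combinations(labels, 2):
            shared = sorted(set(stats[a]) & set(stats[b]))
            if not shared and q == "fl":
                raise ValueError(f"cohorts {a!r} and {b!r} share no age band")
            for band in shared:
                ma, sa = stats[a][band]
                mb, sb = stats[b][band]
                rows.append({
                    "quantity": q, "band": f"{band[0]}-{band[1]}",
                    "cohort_a": a, "cohort_b": b,
                    "mean_a": ma, "mean_b": mb, "sd_a": sa, "sd_b": sb,
                    "overlap": bool(abs(ma - mb) <= 2.0 * (sa + sb)),
                })
    return TimeShiftReport(frame=pd.DataFrame(rows), trajectories=trajs)


def external_compare_v3(
    traj: TrajectoryResult,
    external: Mapping[tuple[int, int], Iterable[float]],
    quantity: str = "fl",
) -> ExternalReport:
    """Compare band means against externally observed prevalences (V-3).

    ``external`` maps an age band to the prevalences observed in other
    populations (user-supplied; at least one value per band).  The report
    records the simulated band mean, the external min-max range, the
    difference from the external midpoint, and whether the simulated value
    falls inside the range.  Bands absent from the trajectory are marked
    not comparable rather than failing.
    """
    if not external:
        raise ValueError("external comparison table is empty")
    rows = []
    for band in sorted(external):
        vals = [float(v) for v in np.atleast_1d(list(external[band]))]
        if not vals:
            raise ValueError(f"no external values for band {band}")
        sim = traj.band_mean(quantity, band)
        lo, hi = min(vals), max(vals)
        comparable = not np.isnan(sim)
        rows.append({
            "band": f"{band[0]}-{band[1]}",
            "sim_mean": sim,
            "ext_min": lo, "ext_max": hi,
            "difference": sim - (lo + hi) / 2.0 if comparable else float("nan"),
            "inside": bool(lo <= sim <= hi) if comparable else False,
            "comparable": comparable,
        })
    return ExternalReport(frame=pd.DataFrame(rows))
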