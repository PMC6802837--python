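"""Individual-level Monte Carlo projection of fatty-liver life-courses.

Each cohort member is advanced one year at a time: continuous covariates
(BMI and the LDL/HDL ratio) are updated by their fitted autoregressive
rules plus a Gaussian residual, the binary risk flags are recomputed, and
next year's disease status is drawn Bernoulli at the main-effects
transition probability.  The projected prevalence is the mean over a small
number of replicate runs (default 10) and its uncertainty band is +/-2
standard deviations across runs ("Monte Carlo variation").

Perturbation semantics for sensitivity analysis: the per-variable
multiplier scales each year's predicted (pre-residual) value, so a 1%
perturbation compounds over the projection horizon.  Replicate runs use
seeds derived from (seed, run index), so two projections with the same
seed but different perturbations are paired on their random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CovariateUpdateModel, FLTransitionModel, transition_probability
from .risk import RiskThresholds

__all__ = [
    "SimulationConfig",
    "TrajectoryResult",
    "baseline_state",
    "simulate_year",
    "simulate_lifecourse",
    "band_coverage",
]

#: physiologic bounds enforced on simulated covariates by residual resampling
BOUNDS = {"bmi": (12.0, 60.0), "ratio": (1e-3, 10.0)}


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo projection protocol.

    ``horizon`` (years) takes precedence; otherwise members are projected
    until the cohort mean age reaches ``target_age`` (default 75, the
    midpoint of the 70-79 band).  ``perturbation`` maps variable name to a
    multiplicative annual-update modifier (1.0 = unperturbed).  The
    population is closed: no entry, exit or death during projection.
    """

    n_runs: int = 10
    horizon: int | None = None
    target_age: int = 75
    seed: int = 0
    perturbation: Mapping[str, float] = field(default_factory=dict)
    closed_population: bool = True
    thresholds: RiskThresholds = field(default_factory=RiskThresholds)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.horizon is not None and self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for name, mult in self.perturbation.items():
            if not mult > 0:
                raise ValueError(f"perturbation for {name!r} must be > 0, got {mult}")


@dataclass
class TrajectoryResult:
    """Per-year mean and across-run SD of the projected prevalences.

    ``frame`` columns: ``year`` (0 = baseline), ``mean_age``, and
    ``{q}_mean``/``{q}_sd`` for q in fl, bmi (BMI>=25 flag) and ratio
    (LDL/HDL>=2 flag).  All prevalences are proportions in [0, 1].
    """

    frame: pd.DataFrame
    n_runs: int
    seed: int

    QUANTITIES = ("fl", "bmi", "ratio")

    def band_mean(self, quantity: str, age_band: tuple[int, int]) -> float:
        """Mean projected prevalence over years whose cohort mean age falls
        in ``age_band`` (inclusive decade band, e.g. (50, 59))."""
        lo, hi = age_band
        rows = self.frame[(self.frame["mean_age"] >= lo) & (self.frame["mean_age"] < hi + 1)]
        if rows.empty:
            return float("nan")
        return float(rows[f"{quantity}_mean"].mean())

    def band_sd(self, quantity: str, age_band: tuple[int, int]) -> float:
        lo, hi = age_band
        rows = self.frame[(self.frame["mean_age"] >= lo) & (self.frame["mean_age"] < hi + 1)]
        if rows.empty:
            return float("nan")
        return float(rows[f"{quantity}_sd"].mean())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plot(self, path, quantity: str = "fl", observed: Mapping[int, float] | None = None,
             label: str = "projected prevalence") -> None:
        """Trajectory with its +/-2 SD Monte Carlo band, written to file."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        f = self.frame
        m, s = f[f"{quantity}_mean"], f[f"{quantity}_sd"]
        fig, ax = plt.subplots(figsize=(7, 4.5))
        ax.fill_between(f["mean_age"], m - 2 * s, m + 2 * s,
                        color="0.8", label="mean +/- 2 SD (Monte Carlo)")
        ax.plot(f["mean_age"], m, color="tab:blue", label=label)
        if observed:
            ys = sorted(observed)
            ages = np.interp(ys, f["year"], f["mean_age"])
            ax.plot(ages, [observed[y] for y in ys], "o", color="tab:red",
                    label="observed")
        ax.set_xlabel("cohort mean age (years)")
        ax.set_ylabel("prevalence")
        ax.set_ylim(0, None)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def baseline_state(panel, thresholds: RiskThresholds | None = None) -> pd.DataFrame:
    """Member state at projection start: first wave per person.

    Requires observed (or imputed) fatty-liver status for every member.
    The LDL/HDL ratio becomes a state variable; LDL and HDL themselves are
    not advanced (the ratio, not its components, enters the model).
    """
    base = panel.baseline() if hasattr(panel, "baseline") else panel.copy()
    if base["fl"].isna().any():
        n = int(base["fl"].isna().sum())
        raise ValueError(
            f"{n} members lack baseline fatty-liver status; impute before simulating"
        )
    state = pd.DataFrame(
        {
            "person_id": base["person_id"].to_numpy(),
            "age": base["age"].to_numpy(dtype=float),
            "fl": base["fl"].to_numpy(dtype=float),
            "bmi": base["bmi"].to_numpy(dtype=float),
            "ratio": (base["ldl"] / base["hdl"]).to_numpy(dtype=float),
        }
    )
    return state


def _bounded_residuals(pred: np.ndarray, sd: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Prediction plus Gaussian residual, resampled into [lo, hi]."""
    if sd <= 0:
        return np.clip(pred, lo, hi)
    out = pred + rng.normal(0.0, sd, len(pred))
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = pred[bad] + rng.normal(0.0, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def simulate_year(
    state: pd.DataFrame,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    rng: np.random.Generator,
    perturbation: Mapping[str, float] | None = None,
    thresholds: RiskThresholds | None = None,
) -> pd.DataFrame:
    """Advance every member by one year.

    Covariates named in ``update_models`` get ``prediction * perturbation``
    plus a residual draw (bounded physiologically); covariates without an
    update model are carried forward frozen.  Risk flags are recomputed
    from the new covariates; status is drawn at the transition probability
    of the member's pre-transition cell; age increments by 1.
    """
    thresholds = thresholds or RiskThresholds()
    perturbation = perturbation or {}
    for name in perturbation:
        if name not in ("bmi", "ratio"):
            raise ValueError(f"no simulated covariate named {name!r}")
    new = state.copy()
    # (1) pre-transition flags come from the current (time-t) covariates
    bmi_flag = (state["bmi"] >= thresholds.bmi_hi).to_numpy(dtype=float)
    ratio_flag = (state["ratio"] >= thresholds.ratio_hi).to_numpy(dtype=float)
    # (2) annual covariate updates
    for name in ("bmi", "ratio"):
        if name in update_models:
            model = update_models[name]
            mult = perturbation.get(name, 1.0)
            lo, hi = BOUNDS[name]
            eta = np.asarray(model.linear_predictor(state[name].to_numpy(),
                                                    state["age"].to_numpy()), dtype=float)
            if model.scale == "log":
                # perturbation multiplies the predicted (natural-scale) value
                eta = eta + np.log(mult)
                drawn = _bounded_residuals(eta, model.resid_sd,
                                           np.log(lo), np.log(hi), rng)
                new[name] = np.exp(drawn)
            else:
                new[name] = _bounded_residuals(eta * mult, model.resid_sd,
                                               lo, hi, rng)
    missing = set(perturbation) - set(update_models)
    if missing:
        raise ValueError(f"perturbation given for variables without update models: "
                         f"{sorted(missing)}")
    # (3) status transition from the time-t cell
    p = transition_probability(fl_model, state["fl"].to_numpy(dtype=float),
                               bmi_flag, ratio_flag)
    new["fl"] = (rng.random(len(state)) < p).astype(float)
    # (4) ageing
    new["age"] = state["age"].to_numpy() + 1.0
    return new


def _prevalences(state: pd.DataFrame, thresholds: RiskThresholds) -> tuple[float, float, float]:
    return (
        float(state["fl"].mean()),
        float((state["bmi"] >= thresholds.bmi_hi).mean()),
        float((state["ratio"] >= thresholds.ratio_hi).mean()),
    )


def simulate_lifecourse(
    cohort,
    fl_model: FLTransitionModel,
    update_models: Mapping[str, CovariateUpdateModel],
    config: SimulationConfig,
) -> TrajectoryResult:
    """Replicate Monte Carlo projection of a cohort's life-course.

    ``cohort`` is a panel (its first wave is the baseline) or a ready-made
    state frame.  ``config.n_runs`` independent replicates start from the
    same baseline; the result holds per-year means and across-run SDs.
    Deterministic given ``config.seed``.
    """
    state0 = cohort if isinstance(cohort, pd.DataFrame) and "ratio" in cohort.columns \
        else baseline_state(cohort, config.thresholds)
    if config.horizon is not None:
        horizon = config.horizon
    else:
        horizon = max(1, int(round(config.target_age - state0["age"].mean())))
    n_years = horizon + 1  # including baseline
    traj = np.empty((config.n_runs, n_years, 3))
    ages = np.empty(n_years)
    ages[:] = [state0["age"].mean() + t for t in range(n_years)]
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run])
        state = state0
        traj[run, 0] = _prevalences(state, config.thresholds)
        for t in range(1, n_years):
            state = simulate_year(state, fl_model, update_models, rng,
                                  config.perturbation, config.thresholds)
            traj[run, t] = _prevalences(state, config.thresholds)
    mean = traj.mean(axis=0)
    sd = traj.std(axis=0, ddof=0) if config.n_runs > 1 else np.zeros_like(mean)
    frame = pd.DataFrame({
        "year": np.arange(n_years),
        "mean_age": ages,
        "fl_mean": mean[:, 0], "fl_sd": sd[:, 0],
        "bmi_mean": mean[:, 1], "bmi_sd": sd[:, 1],
        "ratio_mean": mean[:, 2], "ratio_sd": sd[:, 2],
    })
    return TrajectoryResult(frame=frame, n_runs=config.n_runs, seed=config.seed)


def band_coverage(traj: TrajectoryResult, observed: Mapping[int, float],
                  quantity: str = "fl") -> pd.Series:
    """Whether each observed prevalence falls inside the +/-2 SD band.

    ``observed`` maps projection year (0 = baseline) to prevalence.  Years
    absent from the trajectory are rejected.
    """
    f = traj.frame.set_index("year")
    missing = [y for y in observed if y not in f.index]
    if missing:
        raise ValueError(f"observed years {missing} not in the trajectory")
    years = sorted(observed)
    mean = f.loc[years, f"{quantity}_mean"].to_numpy()
    sd = f.loc[years, f"{quantity}_sd"].to_numpy()
    obs = np.array([observed[y] for y in years], dtype=float)
    return pd.Series(np.abs(obs - mean) <= 2.0 * sd, index=pd.Index(years, name="year"))
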