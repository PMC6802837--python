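"""Transition and annual-update models for the fatty-liver microsimulation.

The disease state is binary (fatty liver present/absent by ultrasonography).
Its one-year transition probability is a main-effects logistic in three
binary predictors measured before transition: current status, the BMI >= 25
flag and the LDL-C/HDL-C >= 2 flag.  The eight resulting probabilities form
the published transition table (:data:`PUBLISHED_TRANSITION_TABLE`).

Continuous risk factors are advanced one year at a time by first-order
autoregressive update rules with Gaussian residuals, fitted from panel data
(:func:`fit_covariate_update`).  Missing disease status in the youngest age
bands is imputed from a same-year logistic model (:func:`impute_missing_fl`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit, logit

from .risk import FLAG_NAMES, LIFESTYLE_FIELDS, RiskThresholds, flag_frame

__all__ = [
    "PUBLISHED_TRANSITION_TABLE",
    "FLTransitionModel",
    "TransitionTable",
    "transition_probability",
    "build_table",
    "fit_table_main_effects",
    "stationary_prevalence",
    "fit_fl_transition",
    "CovariateUpdateModel",
    "fit_covariate_update",
    "ImputationModel",
    "fit_imputation_model",
    "impute_missing_fl",
    "person_year_pairs",
]

#: Published annual transition probabilities to fatty-liver presence, indexed
#: by (current status, BMI>=25 flag, LDL/HDL>=2 flag).  These eight numbers
#: are the model's empirical anchor.
PUBLISHED_TRANSITION_TABLE: dict[tuple[int, int, int], float] = {
    (0, 0, 0): 0.031,
    (0, 0, 1): 0.074,
    (0, 1, 0): 0.072,
    (0, 1, 1): 0.164,
    (1, 0, 0): 0.649,
    (1, 0, 1): 0.823,
    (1, 1, 0): 0.819,
    (1, 1, 1): 0.919,
}

_CELLS = tuple(sorted(PUBLISHED_TRANSITION_TABLE))


@dataclass
class FLTransitionModel:
    """Main-effects logistic model for next-year fatty-liver presence.

    Log-odds of presence at t+1 are
    ``beta0 + fl*beta_fl + bmi_flag*beta_bmi + ratio_flag*beta_ratio``
    where ``fl`` is current presence and the flags are the dichotomized
    BMI and cholesterol-ratio states at t.  No interaction terms.
    """

    beta0: float
    beta_fl: float
    beta_bmi: float
    beta_ratio: float
    fit_info: dict | None = field(default=None, compare=False, repr=False)

    def validate(self) -> "FLTransitionModel":
        """Check the risk-increasing sign pattern implied by the table."""
        for name in ("beta_fl", "beta_bmi", "beta_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 for a risk-increasing model")
        return self

    def to_dict(self) -> dict:
        return {
            "beta0": float(self.beta0),
            "beta_fl": float(self.beta_fl),
            "beta_bmi": float(self.beta_bmi),
            "beta_ratio": float(self.beta_ratio),
        }

    @classmethod
    def published(cls) -> "FLTransitionModel":
        """Model recovered from the published 8-cell transition table."""
        return fit_table_main_effects(PUBLISHED_TRANSITION_TABLE)


@dataclass(frozen=True)
class TransitionTable:
    """The 8 annual transition probabilities induced by a main-effects model."""

    cells: Mapping[tuple[int, int, int], float]

    def __post_init__(self) -> None:
        for key in _CELLS:
            if key not in self.cells:
                raise ValueError(f"transition table missing cell {key}")
            p = self.cells[key]
            if not 0.0 < p < 1.0:
                raise ValueError(f"cell {key} probability {p} outside (0, 1)")

    def __getitem__(self, key: tuple[int, int, int]) -> float:
        return self.cells[key]

    def is_monotone(self) -> bool:
        """Nondecreasing in each of the three binary indices."""
        for (f, b, r), p in self.cells.items():
            for axis in range(3):
                idx = [f, b, r]
                if idx[axis] == 0:
                    idx[axis] = 1
                    if self.cells[tuple(idx)] < p:
                        return False
        return True

    def to_frame(self) -> pd.DataFrame:
        """Long layout: one row per cell, matching the published table."""
        rows = [
            {"fatty_liver": f, "bmi_ge_25": b, "ldl_hdl_ge_2": r, "probability": p}
            for (f, b, r), p in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def transition_probability(
    model: FLTransitionModel, fl, bmi_flag, ratio_flag
):
    """Annual probability of fatty-liver presence next year.

    Accepts scalars or numpy arrays for the three binary predictors.
    """
    eta = (
        model.beta0
        + np.asarray(fl, dtype=float) * model.beta_fl
        + np.asarray(bmi_flag, dtype=float) * model.beta_bmi
        + np.asarray(ratio_flag, dtype=float) * model.beta_ratio
    )
    out = expit(eta)
    return float(out) if np.ndim(out) == 0 else out


def build_table(model: FLTransitionModel) -> TransitionTable:
    """Evaluate the model at all 8 predictor combinations."""
    return TransitionTable(
        {(f, b, r): transition_probability(model, f, b, r) for (f, b, r) in _CELLS}
    )


def fit_table_main_effects(
    cells: Mapping[tuple[int, int, int], float]
) -> FLTransitionModel:
    """Recover a main-effects logistic surface from transition-table cells.

    Unweighted least squares of the cell log-odds on an intercept plus the
    three binary indicators.  Cell-level sample sizes are not published, so
    no weighting is possible; with all 8 cells the fit doubles as a check
    that the table is additive on the logit scale.  At least 4 cells
    spanning all three indices (full-rank design) are required.
    """
    keys = sorted(cells)
    if len(keys) < 4:
        raise ValueError(f"need >= 4 cells to identify 4 coefficients, got {len(keys)}")
    X = np.array([[1.0, f, b, r] for (f, b, r) in keys])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design: cells do not span all three indices")
    y = logit(np.array([cells[k] for k in keys], dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return FLTransitionModel(
        beta0=float(beta[0]),
        beta_fl=float(beta[1]),
        beta_bmi=float(beta[2]),
        beta_ratio=float(beta[3]),
        fit_info={"n_cells": len(keys), "logit_rss": float(resid @ resid)},
    )


def stationary_prevalence(p01: float, p11: float) -> float:
    """Long-run prevalence of a two-state chain with frozen covariates.

    ``p01`` is the incidence probability (absent -> present) and ``p11`` the
    persistence probability (present -> present); the fixed point is
    ``p01 / (p01 + 1 - p11)``.
    """
    if not (0.0 <= p01 <= 1.0 and 0.0 <= p11 <= 1.0):
        raise ValueError("p01 and p11 must lie in [0, 1]")
    denom = p01 + 1.0 - p11
    if denom <= 0.0:
        raise ValueError("degenerate chain: p01 = 0 and p11 = 1 has no unique fixed point")
    return p01 / denom


# ---------------------------------------------------------------------------
# fitting from panels

def person_year_pairs(panel, columns: Sequence[str] = ()) -> pd.DataFrame:
    """Consecutive-year (t, t+1) pairs for every person in a panel.

    Returns a frame with ``person_id``, ``year``, ``age`` (at t), ``fl_t``,
    ``fl_t1`` and, for each requested column ``c``, ``{c}_t`` and ``{c}_t1``.
    Rows are kept regardless of missingness; callers filter.
    """
    df = getattr(panel, "df", panel)
    df = df.sort_values(["person_id", "year"])
    nxt = df.groupby("person_id", sort=False).shift(-1)
    consecutive = nxt["year"] == df["year"] + 1
    out = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "year": df["year"],
            "age": df["age"],
            "fl_t": df["fl"],
            "fl_t1": nxt["fl"],
        }
    )
    for c in columns:
        out[f"{c}_t"] = df[c]
        out[f"{c}_t1"] = nxt[c]
    return out[consecutive.fillna(False)].reset_index(drop=True)


def fit_fl_transition(
    panel,
    candidate_flags: Sequence[str] = ("bmi", "ratio"),
    alpha: float = 0.05,
    thresholds: RiskThresholds | None = None,
) -> FLTransitionModel:
    """Fit the annual fatty-liver transition model from a longitudinal panel.

    Logistic regression of status at t+1 on current status (always kept)
    plus the dichotomized candidate flags at t, followed by backward
    elimination: the candidate with the largest p-value >= ``alpha`` is
    dropped, one per step, until all surviving candidates have p < alpha.
    Ties are broken by candidate order.

    Candidates may be any of the seven abnormality flags or the four
    lifestyle booleans.  The returned model carries the surviving
    coefficients; an eliminated ``bmi``/``ratio`` term is reported as 0.0,
    and elimination details live in ``fit_info``.
    """
    thresholds = thresholds or RiskThresholds()
    df = getattr(panel, "df", panel)
    unknown = set(candidate_flags) - set(FLAG_NAMES) - set(LIFESTYLE_FIELDS)
    if unknown:
        raise ValueError(f"unknown candidate flags: {sorted(unknown)}")

    pairs = person_year_pairs(panel)
    base = df.sort_values(["person_id", "year"]).reset_index(drop=True)
    keep = base.dropna(subset=["fl"]).index
    # build design on the t-side rows; join flags computed from the panel
    flags = flag_frame(base, thresholds)
    for name in LIFESTYLE_FIELDS:
        flags[name] = base[name].astype(bool)
    flags["person_id"] = base["person_id"]
    flags["year"] = base["year"]
    design = pairs.merge(flags, on=["person_id", "year"], how="left")
    design = design.dropna(subset=["fl_t", "fl_t1"])
    if len(design) < 50:
        raise ValueError(
            f"only {len(design)} observed person-transitions; >= 50 required to fit"
        )

    y = design["fl_t1"].astype(float).to_numpy()
    survivors = list(candidate_flags)
    dropped: list[tuple[str, float]] = []
    while True:
        X = pd.DataFrame({"const": 1.0, "fl": design["fl_t"].astype(float)})
        for name in survivors:
            X[name] = design[name].astype(float)
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0)
        except Exception as exc:  # separation, singular Hessian
            raise ValueError(f"logistic fit failed (possible complete separation): {exc}")
        if not np.all(np.isfinite(res.bse)):
            raise ValueError("logistic fit degenerate: infinite standard errors "
                             "(possible complete separation)")
        pvals = dict(zip(["const", "fl", *survivors], res.pvalues))
        worst = max(survivors, key=lambda n: (pvals[n], -survivors.index(n)), default=None)
        if worst is None or pvals[worst] < alpha:
            params = dict(zip(["const", "fl", *survivors], res.params))
            break
        survivors.remove(worst)
        dropped.append((worst, float(pvals[worst])))

    return FLTransitionModel(
        beta0=float(params["const"]),
        beta_fl=float(params["fl"]),
        beta_bmi=float(params.get("bmi", 0.0)),
        beta_ratio=float(params.get("ratio", 0.0)),
        fit_info={
            "n_transitions": int(len(design)),
            "survivors": list(survivors),
            "dropped": dropped,
            "pvalues": {k: float(v) for k, v in pvals.items()},
            "extra_params": {k: float(v) for k, v in params.items()
                             if k not in ("const", "fl", "bmi", "ratio")},
        },
    )


@dataclass
class CovariateUpdateModel:
    """Annual update rule for one continuous covariate.

    On the linear scale next year's value is predicted as
    ``intercept + slope*value + age_coef*age + age2_coef*age^2`` plus a
    Gaussian residual with standard deviation ``resid_sd`` (same units as
    the variable).  With ``scale="log"`` the same autoregression is applied
    to log(value), with the residual on the log scale — the natural form
    for positive, multiplicatively-noisy quantities such as the LDL/HDL
    ratio, where a homoscedastic linear-scale residual inflates
    threshold-crossing rates when iterated.  Fitted by ordinary least
    squares on consecutive-year pairs.
    """

    variable: str
    intercept: float
    slope: float
    age_coef: float = 0.0
    age2_coef: float = 0.0
    resid_sd: float = 0.0
    n_pairs: int = 0
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def linear_predictor(self, value, age):
        """Deterministic prediction on the model's own scale (log scale for
        ``scale='log'``); residuals are added on this scale."""
        x = np.asarray(value, dtype=float)
        if self.scale == "log":
            x = np.log(x)
        age = np.asarray(age, dtype=float)
        out = self.intercept + self.slope * x + self.age_coef * age + self.age2_coef * age**2
        return float(out) if np.ndim(out) == 0 else out

    def predict(self, value, age):
        """Deterministic one-year-ahead prediction on the natural scale."""
        eta = self.linear_predictor(value, age)
        return float(np.exp(eta)) if self.scale == "log" and np.ndim(eta) == 0 \
            else (np.exp(eta) if self.scale == "log" else eta)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (v if isinstance(v, (str, int)) else float(v)) for k, v in d.items()}


def fit_covariate_update(
    panel, variable: str, age_terms: bool = True, min_pairs: int = 50,
    scale: str | None = None,
) -> CovariateUpdateModel:
    """Fit the annual autoregressive update for one continuous covariate.

    OLS of value(t+1) on value(t) plus (by default) linear and quadratic
    age-profile terms; the residual SD comes from the fit residuals with a
    degrees-of-freedom correction.  ``variable`` may be any continuous
    column or ``"ratio"`` (computed as LDL/HDL on the fly).  ``scale``
    defaults to "log" for the ratio and "linear" otherwise.
    """
    df = getattr(panel, "df", panel).copy()
    if variable == "ratio":
        df["ratio"] = df["ldl"] / df["hdl"]
    if variable not in df.columns:
        raise ValueError(f"panel has no column {variable!r}")
    if scale is None:
        scale = "log" if variable == "ratio" else "linear"
    pairs = person_year_pairs(df, columns=[variable]).dropna(
        subset=[f"{variable}_t", f"{variable}_t1"]
    )
    if len(pairs) < min_pairs:
        raise ValueError(
            f"only {len(pairs)} pairs for {variable!r}; >= {min_pairs} required"
        )
    y = pairs[f"{variable}_t1"].to_numpy(dtype=float)
    x = pairs[f"{variable}_t"].to_numpy(dtype=float)
    if scale == "log":
        if (y <= 0).any() or (x <= 0).any():
            raise ValueError(f"log-scale update for {variable!r} requires positive values")
        y, x = np.log(y), np.log(x)
    cols = [np.ones(len(pairs)), x]
    if age_terms:
        a = pairs["age"].to_numpy(dtype=float)
        cols += [a, a**2]
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit()
    dof = max(len(pairs) - X.shape[1], 1)
    resid_sd = float(np.sqrt(np.sum(res.resid**2) / dof))
    params = res.params
    return CovariateUpdateModel(
        variable=variable,
        intercept=float(params[0]),
        slope=float(params[1]),
        age_coef=float(params[2]) if age_terms else 0.0,
        age2_coef=float(params[3]) if age_terms else 0.0,
        resid_sd=resid_sd,
        n_pairs=int(len(pairs)),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# imputation of missing fatty-liver status

@dataclass
class ImputationModel:
    """Same-year logistic model for fatty-liver presence given risk flags.

    Used to fill in disease status where ultrasonography coverage is
    incomplete (the youngest age bands).  ``terms`` name the design columns:
    abnormality flags, lifestyle booleans and/or ``"age"``.
    """

    terms: tuple[str, ...]
    intercept: float
    coefs: tuple[float, ...]
    n_obs: int = 0

    def predict_proba(self, df: pd.DataFrame, thresholds: RiskThresholds | None = None):
        thresholds = thresholds or RiskThresholds()
        flags = flag_frame(df, thresholds)
        eta = np.full(len(df), self.intercept, dtype=float)
        for name, coef in zip(self.terms, self.coefs):
            if name == "age":
                x = df["age"].to_numpy(dtype=float)
            elif name in flags.columns:
                x = flags[name].to_numpy(dtype=float)
            elif name in df.columns:
                x = df[name].astype(float).to_numpy()
            else:
                raise ValueError(f"imputation term {name!r} absent from panel")
            eta += coef * x
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "intercept": float(self.intercept),
            "coefs": [float(c) for c in self.coefs],
            "n_obs": int(self.n_obs),
        }


def fit_imputation_model(
    panel,
    terms: Sequence[str] = ("bmi", "ratio", "age"),
    age_range: tuple[int, int] = (30, 69),
    thresholds: RiskThresholds | None = None,
) -> ImputationModel:
    """Fit the same-year status model on observed records in ``age_range``."""
    thresholds = thresholds or RiskThresholds()
    df = getattr(panel, "df", panel)
    obs = df[(df["age"] >= age_range[0]) & (df["age"] <= age_range[1]) & df["fl"].notna()]
    if len(obs) < 50:
        raise ValueError(f"only {len(obs)} observed records in {age_range}; >= 50 required")
    flags = flag_frame(obs, thresholds)
    X = [np.ones(len(obs))]
    for name in terms:
        if name == "age":
            X.append(obs["age"].to_numpy(dtype=float))
        elif name in flags.columns:
            X.append(flags[name].to_numpy(dtype=float))
        elif name in obs.columns:
            X.append(obs[name].astype(float).to_numpy())
        else:
            raise ValueError(f"imputation term {name!r} absent from panel")
    res = sm.Logit(obs["fl"].astype(float).to_numpy(), np.column_stack(X)).fit(disp=0)
    return ImputationModel(
        terms=tuple(terms),
        intercept=float(res.params[0]),
        coefs=tuple(float(c) for c in res.params[1:]),
        n_obs=int(len(obs)),
    )


def impute_missing_fl(panel, model: ImputationModel, seed: int,
                      thresholds: RiskThresholds | None = None):
    """Replace missing fatty-liver statuses by Bernoulli draws from ``model``.

    Observed statuses are never altered; the result is deterministic given
    ``seed``.  Returns an object of the same panel type.
    """
    from .cohort import CohortPanel  # local import to avoid a cycle

    df = getattr(panel, "df", panel).copy()
    missing = df["fl"].isna()
    if missing.any():
        probs = model.predict_proba(df.loc[missing], thresholds)
        rng = np.random.default_rng(seed)
        df.loc[missing, "fl"] = (rng.random(int(missing.sum())) < probs).astype(float)
    meta = dict(getattr(panel, "meta", {}) or {})
    meta["imputed_fl"] = int(missing.sum())
    return CohortPanel(df, meta=meta)


def models_to_yaml(path, fl_model: FLTransitionModel,
                   update_models: Mapping[str, CovariateUpdateModel],
                   imputation: ImputationModel | None = None) -> None:
    """Serialize fitted models (coefficients, residual SDs, sample sizes)."""
    payload = {
        "fl_transition": fl_model.to_dict(),
        "covariate_updates": {k: m.to_dict() for k, m in update_models.items()},
    }
    if imputation is not None:
        payload["imputation"] = imputation.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
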