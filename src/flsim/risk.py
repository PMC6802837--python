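"""Dichotomization of continuous risk factors into normal/abnormal categories.

The transition model and the sensitivity analysis operate on binary risk
flags, not raw values.  Cut-offs follow the risk-stratification guidelines
used in Japanese health examinations: BMI >= 25 kg/m2, LDL-C >= 120 mg/dl,
HDL-C < 40 mg/dl, LDL-C/HDL-C >= 2, TG >= 150 mg/dl, SBP >= 130 mmHg and
HbA1c >= 6.5 %.  ">="-type rules are inclusive at the boundary; the HDL rule
is strictly "<".
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "RiskThresholds",
    "RiskCategoryProfile",
    "ldl_hdl_ratio",
    "dichotomize",
    "flag_frame",
    "CONTINUOUS_FIELDS",
    "LIFESTYLE_FIELDS",
    "FLAG_NAMES",
]

#: continuous covariates carried by a person-year record
CONTINUOUS_FIELDS = ("bmi", "ldl", "hdl", "tg", "sbp", "hba1c")
#: self-reported lifestyle booleans (fixed per person)
LIFESTYLE_FIELDS = ("smoker", "drinker", "exerciser", "shiftworker")
#: binary abnormality flags produced by :func:`dichotomize`
FLAG_NAMES = ("bmi", "ldl", "hdl", "ratio", "tg", "sbp", "hba1c")


@dataclass(frozen=True)
class RiskThresholds:
    """Cut-offs separating normal from abnormal covariate values."""

    bmi_hi: float = 25.0     # kg/m2, abnormal if >=
    ldl_hi: float = 120.0    # mg/dl, abnormal if >=
    hdl_lo: float = 40.0     # mg/dl, abnormal if <
    ratio_hi: float = 2.0    # unitless LDL-C/HDL-C, abnormal if >=
    tg_hi: float = 150.0     # mg/dl, abnormal if >=
    sbp_hi: float = 130.0    # mmHg, abnormal if >=
    hba1c_hi: float = 6.5    # %, abnormal if >=

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RiskThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class RiskCategoryProfile:
    """Abnormality flags for one person-year, plus the lifestyle booleans.

    Each flag is a pure function of the record and the thresholds.
    """

    bmi: bool
    ldl: bool
    hdl: bool
    ratio: bool
    tg: bool
    sbp: bool
    hba1c: bool
    smoker: bool = False
    drinker: bool = False
    exerciser: bool = False
    shiftworker: bool = False


def ldl_hdl_ratio(ldl: float, hdl: float) -> float:
    """LDL-C/HDL-C cholesterol ratio (unitless).

    Parameters are in mg/dl; ``hdl`` must be strictly positive.
    """
    if not hdl > 0:
        raise ValueError(f"hdl must be > 0 to form the LDL/HDL ratio, got {hdl}")
    return ldl / hdl


def dichotomize(record: Mapping, thresholds: RiskThresholds | None = None) -> RiskCategoryProfile:
    """Categorize one person-year record into normal/abnormal risk flags.

    ``record`` is any mapping (dict, pandas Series, dataclass ``__dict__``)
    holding the six continuous fields; lifestyle booleans are passed through
    if present.  A missing or NA continuous field is rejected by name.
    """
    thresholds = thresholds or RiskThresholds()
    vals = {}
    for name in CONTINUOUS_FIELDS:
        if name not in record or pd.isna(record[name]):
            raise ValueError(f"cannot dichotomize: continuous field {name!r} is missing")
        vals[name] = float(record[name])
    ratio = ldl_hdl_ratio(vals["ldl"], vals["hdl"])
    return RiskCategoryProfile(
        bmi=vals["bmi"] >= thresholds.bmi_hi,
        ldl=vals["ldl"] >= thresholds.ldl_hi,
        hdl=vals["hdl"] < thresholds.hdl_lo,
        ratio=ratio >= thresholds.ratio_hi,
        tg=vals["tg"] >= thresholds.tg_hi,
        sbp=vals["sbp"] >= thresholds.sbp_hi,
        hba1c=vals["hba1c"] >= thresholds.hba1c_hi,
        smoker=bool(record.get("smoker", False)) if hasattr(record, "get") else False,
        drinker=bool(record.get("drinker", False)) if hasattr(record, "get") else False,
        exerciser=bool(record.get("exerciser", False)) if hasattr(record, "get") else False,
        shiftworker=bool(record.get("shiftworker", False)) if hasattr(record, "get") else False,
    )


def flag_frame(df: pd.DataFrame, thresholds: RiskThresholds | None = None) -> pd.DataFrame:
    """Vectorized :func:`dichotomize` over a person-year table.

    Returns a boolean DataFrame with columns :data:`FLAG_NAMES`, aligned on
    the input index.  Rows with a missing continuous field are rejected.
    """
    thresholds = thresholds or RiskThresholds()
    for name in CONTINUOUS_FIELDS:
        if name not in df.columns:
            raise ValueError(f"cannot dichotomize: column {name!r} is missing")
        if df[name].isna().any():
            raise ValueError(f"cannot dichotomize: column {name!r} has missing values")
    if (df["hdl"] <= 0).any():
        raise ValueError("hdl must be > 0 to form the LDL/HDL ratio")
    ratio = df["ldl"] / df["hdl"]
    out = pd.DataFrame(
        {
            "bmi": df["bmi"] >= thresholds.bmi_hi,
            "ldl": df["ldl"] >= thresholds.ldl_hi,
            "hdl": df["hdl"] < thresholds.hdl_lo,
            "ratio": ratio >= thresholds.ratio_hi,
            "tg": df["tg"] >= thresholds.tg_hi,
            "sbp": df["sbp"] >= thresholds.sbp_hi,
            "hba1c": df["hba1c"] >= thresholds.hba1c_hi,
        },
        index=df.index,
    )
    return out
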