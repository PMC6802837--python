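"""CSV panel serialization.

One row per person-year, columns exactly: person_id, year, age, fl, bmi,
ldl, hdl, tg, sbp, hba1c, smoker, drinker, exerciser, shiftwork.  Fatty
liver is coded 0/1/NA; lifestyle booleans 0/1.  Writing then reading
reproduces the panel exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import CohortPanel, PANEL_COLUMNS

__all__ = ["read_panel", "write_panel", "CSV_COLUMNS"]

#: on-disk header; the in-memory field `shiftworker` is written as `shiftwork`
CSV_COLUMNS = ("person_id", "year", "age", "fl", "bmi", "ldl", "hdl", "tg",
               "sbp", "hba1c", "smoker", "drinker", "exerciser", "shiftwork")

_TO_DISK = {"shiftworker": "shiftwork"}
_FROM_DISK = {v: k for k, v in _TO_DISK.items()}
_BOOL_COLS = ("smoker", "drinker", "exerciser", "shiftwork")


def write_panel(panel: CohortPanel, path) -> None:
    """Serialize a panel to CSV with the canonical schema."""
    df = panel.df.rename(columns=_TO_DISK).loc[:, list(CSV_COLUMNS)].copy()
    df["fl"] = df["fl"].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    for c in _BOOL_COLS:
        df[c] = df[c].astype(int)
    for c in ("bmi", "ldl", "hdl", "tg", "sbp", "hba1c"):
        df[c] = df[c].map(repr)  # shortest round-trip representation
    df.to_csv(path, index=False)


def read_panel(path) -> CohortPanel:
    """Read a panel CSV, validating the schema row by row.

    Unknown columns are dropped with a warning; a malformed value is
    rejected with its (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "fl": str},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing columns: {missing}")

    fl = pd.Series(np.nan, index=df.index, dtype=float)
    for i, raw in enumerate(df["fl"]):
        v = raw.strip()
        if v in ("NA", "", "nan"):
            continue
        if v not in ("0", "1"):
            raise ValueError(f"row {i + 1}: fl must be 0, 1 or NA, got {raw!r}")
        fl.iloc[i] = float(v)
    out = df.copy()
    out["fl"] = fl
    for c in ("year", "age"):
        try:
            out[c] = out[c].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {c!r} must be integer: {exc}")
    for c in ("bmi", "ldl", "hdl", "tg", "sbp", "hba1c"):
        try:
            out[c] = out[c].astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {c!r} must be numeric: {exc}")
    for c in _BOOL_COLS:
        vals = out[c].astype(str).str.strip()
        bad = ~vals.isin(["0", "1", "True", "False"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"row {row + 1}: {c} must be 0/1, got {out[c].iloc[row]!r}")
        out[c] = vals.isin(["1", "True"])
    out = out.rename(columns=_FROM_DISK)
    return CohortPanel(out, meta={"source": str(path)}).validate()
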