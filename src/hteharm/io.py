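"""Reading, validating and summarizing participant-level trial tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prep import covariate_columns
from .simulate import TRUTH_COLUMNS

__all__ = ["read_trial_table", "write_trial_table", "baseline_summary"]

REQUIRED = ("id", "site", "arm", "time", "event")


def read_trial_table(path) -> pd.DataFrame:
    """Load a cohort CSV and validate its schema.

    Required columns: ``id, site, arm, time, event`` with ``time > 0``,
    ``arm`` in {0, 1} (1 = intensive), ``event`` in {0, 1}; every other
    column is treated as a numeric baseline covariate.  Raises ``ValueError``
    naming the missing column or the first offending row.
    """
    df = pd.read_csv(path)
    return validate_trial_table(df)


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED:
        if col not in df.columns:
            raise ValueError(f"trial table is missing required column {col!r}")
    for col, allowed in (("arm", (0, 1)), ("event", (0, 1))):
        vals = df[col]
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"column {col!r} must be in {allowed}; row {row} has {vals.iloc[row]!r}")
    if (df["time"] <= 0).any():
        row = int(np.flatnonzero(df["time"] <= 0)[0])
        raise ValueError(f"column 'time' must be > 0; row {row} has {df['time'].iloc[row]!r}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    for col in covariate_columns(df):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = int(np.flatnonzero(bad)[0]) if bad.any() else 0
            raise ValueError(f"covariate {col!r} has a non-numeric value at row {row}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def baseline_summary(df: pd.DataFrame, partition: pd.Series | None = None) -> pd.DataFrame:
    """Table-1-style description: covariate mean (SD) by arm, optionally by partition.

    Binary covariates are summarized as count (percent); the event indicator
    is included as an outcome row.  Returns a tidy frame with one row per
    (partition, covariate) and formatted treated/control cells.
    """
    work = df.copy()
    for t in TRUTH_COLUMNS:
        work = work.drop(columns=[t], errors="ignore")
    work["_part"] = "overall" if partition is None else partition.to_numpy()
    rows = []
    cols = covariate_columns(work.drop(columns=["_part"])) + ["event"]
    for part, block in work.groupby("_part", sort=False):
        for col in cols:
            cells = {"partition": part, "covariate": col}
            vals = block[col]
            binary = set(np.unique(vals)).issubset({0, 1})
            for aname, aval in (("treated", 1), ("control", 0)):
                v = vals[block["arm"] == aval]
                if binary:
                    cells[f"{aname}_n"] = int(v.sum())
                    cells[f"{aname}_pct"] = round(100.0 * v.mean(), 1) if len(v) else float("nan")
                    cells[aname] = f"{int(v.sum())} ({100.0 * v.mean():.1f})"
                else:
                    cells[aname] = f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
                cells[f"{aname}_mean"] = float(v.mean()) if len(v) else float("nan")
            rows.append(cells)
    return pd.DataFrame(rows)
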