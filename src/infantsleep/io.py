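"""Delimited-text readers and writers.

Dialects (all plain CSV, documented in the README):

* epoch file — ``timestamp`` (ISO-8601) plus either ``activity`` (one row
  per minute) or ``x,y,z`` acceleration in g at the device rate;
* minute grid — the in-memory minute DataFrame, one row per minute;
* diary — one row per 15-min interval: ``day_index``, ``interval_start``
  (HH:MM), ``state`` (S/W), ``external_movement``, ``removed``;
* nights — one row per night: ``night_id``, ``reported_bedtime``,
  ``reported_getup`` in minutes (extended clock; blank when unreported);
* metadata / ASQ — one row per participant-timepoint.

Writers and readers round-trip exactly: floats are serialized with
shortest-repr formatting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MINUTE_COLUMNS = ["minute_index", "clock_min", "day_index", "activity",
                  "wear", "diary_state", "external_movement"]


def write_minutes(minutes: pd.DataFrame, path) -> None:
    cols = [c for c in MINUTE_COLUMNS + ["state"] if c in minutes.columns]
    minutes[cols].to_csv(path, index=False)


def read_minutes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("wear", "external_movement"):
        if col in df:
            df[col] = df[col].astype(bool)
    for col in ("diary_state", "state"):
        if col in df:
            df[col] = df[col].astype(np.int8)
    return df


def read_epochs(path):
    """Read an epoch file; returns ('counts', series) for pre-computed
    per-minute activity or ('accel', (t, xyz)) for raw acceleration."""
    df = pd.read_csv(path)
    if "activity" in df.columns:
        return "counts", df["activity"].to_numpy(dtype=float)
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError("epoch file needs 'activity' or 'x','y','z'")
    t = pd.to_datetime(df["timestamp"])
    secs = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    return "accel", (secs, df[["x", "y", "z"]].to_numpy(dtype=float))


def _hhmm(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


def write_diary(diary: pd.DataFrame, path) -> None:
    out = diary.copy()
    out["interval_start"] = out["interval_start"].map(_hhmm)
    out.to_csv(path, index=False)


def read_diary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    hm = df["interval_start"].str.split(":", expand=True).astype(int)
    df["interval_start"] = hm[0] * 60 + hm[1]
    return df


def write_nights(nights: pd.DataFrame, path) -> None:
    nights.to_csv(path, index=False)


def read_nights(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, index=index)


def read_matrix(path) -> pd.DataFrame:
    """Read a wide assessment matrix keyed by participant/timepoint."""
    df = pd.read_csv(path)
    if {"participant", "timepoint"} <= set(df.columns):
        df = df.set_index(["participant", "timepoint"])
    return df
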