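"""Raw acceleration -> per-minute activity counts, non-wear detection,
and fusion with the 24-h diary.

The count pipeline follows standard ankle-actimetry practice: each axis is
band-pass filtered (3-11 Hz, 4th-order Butterworth applied forward-backward
for zero phase), rectified and compressed to 15-s bins, the three axes are
fused per bin by sum of squares, and four bins are summed into one count
per minute.  The 15-s bin statistic (sum of absolute filtered values) is
configurable because devices and toolchains differ on this point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import DIARY_SLEEP, DIARY_UNKNOWN, DIARY_WAKE, MINUTES_PER_DAY

_BIN_STATS = {"sum": np.sum, "mean": np.mean, "max": np.max}


@dataclass(frozen=True)
class CountConfig:
    """Parameters of the acceleration -> count conversion."""

    low_hz: float = 3.0
    high_hz: float = 11.0
    order: int = 4
    bin_seconds: int = 15
    bin_stat: str = "sum"  # statistic over |filtered| within a 15-s bin


def accel_to_counts(accel: np.ndarray, rate: float,
                    cfg: CountConfig = CountConfig()) -> np.ndarray:
    """Convert a contiguous tri-axial acceleration block to per-minute counts.

    Parameters
    ----------
    accel : (n_samples, 3) array of acceleration in g.
    rate : sampling rate in Hz; must exceed twice the filter's upper edge.

    Returns
    -------
    (n_minutes,) float array of activity counts; trailing samples that do
    not fill a whole minute are dropped.  Counts are >= 0 by construction.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError("accel must have shape (n_samples, 3)")
    if rate <= 2 * cfg.high_hz:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {cfg.high_hz} Hz band edge")
    if cfg.bin_stat not in _BIN_STATS:
        raise ValueError(f"unknown bin_stat {cfg.bin_stat!r}")

    sos = signal.butter(cfg.order, [cfg.low_hz, cfg.high_hz],
                        btype="bandpass", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, accel, axis=0)

    samples_per_bin = int(round(rate * cfg.bin_seconds))
    n_bins = filtered.shape[0] // samples_per_bin
    if n_bins == 0:
        return np.zeros(0)
    stat = _BIN_STATS[cfg.bin_stat]
    trimmed = np.abs(filtered[: n_bins * samples_per_bin])
    binned = stat(trimmed.reshape(n_bins, samples_per_bin, 3), axis=1)
    fused = np.sum(binned ** 2, axis=1)  # sum of squares across axes

    bins_per_min = 60 // cfg.bin_seconds
    n_min = n_bins // bins_per_min
    return fused[: n_min * bins_per_min].reshape(n_min, bins_per_min).sum(axis=1)


def detect_nonwear(counts: np.ndarray,
                   diary_removed: np.ndarray | None = None,
                   zero_run_minutes: int = 60) -> np.ndarray:
    """Flag non-wear minutes.

    A minute is non-wear when the diary reports the device removed, or when
    it falls in a run of zero counts longer than ``zero_run_minutes``
    (stand-in for the visual inspection of abrupt no-activity periods).
    Returns a boolean wear mask (True = worn).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    wear = np.ones(n, dtype=bool)
    if diary_removed is not None:
        removed = np.asarray(diary_removed, dtype=bool)
        if removed.size != n:
            raise ValueError("diary_removed length must match counts")
        wear &= ~removed

    # zero-run detection on the count trace (NaN counts as zero-information,
    # not as activity)
    is_zero = (np.nan_to_num(counts, nan=0.0) == 0)
    if n:
        edges = np.flatnonzero(np.diff(is_zero.astype(np.int8)))
        starts = np.r_[0, edges + 1]
        ends = np.r_[edges + 1, n]
        for s, e in zip(starts, ends):
            if is_zero[s] and (e - s) > zero_run_minutes:
                wear[s:e] = False
    return wear


def broadcast_diary(diary: pd.DataFrame, n_minutes: int) -> np.ndarray:
    """Broadcast a 15-min-interval diary to the minute grid.

    ``diary`` rows carry ``day_index``, ``interval_start`` (clock minutes,
    multiple of 15) and ``state`` in {'S','W'} or {DIARY_SLEEP, DIARY_WAKE}.
    Minutes with no diary row get DIARY_UNKNOWN.  Overlapping rows with
    contradictory states raise, naming the offending rows.
    """
    out = np.full(n_minutes, DIARY_UNKNOWN, dtype=np.int8)
    state_map = {"S": DIARY_SLEEP, "W": DIARY_WAKE,
                 DIARY_SLEEP: DIARY_SLEEP, DIARY_WAKE: DIARY_WAKE}
    for idx, row in diary.iterrows():
        start = int(row["day_index"]) * MINUTES_PER_DAY + int(row["interval_start"])
        if start >= n_minutes or start < 0:
            continue
        end = min(start + 15, n_minutes)
        st = state_map[row["state"]]
        seg = out[start:end]
        clash = (seg != DIARY_UNKNOWN) & (seg != st)
        if clash.any():
            raise ValueError(
                f"contradictory diary rows overlap at minute {start}: row {idx}")
        out[start:end] = st
    return out


def fuse_diary(counts: np.ndarray, wear: np.ndarray,
               diary_state: np.ndarray) -> pd.DataFrame:
    """Assemble the minute grid prior to sleep scoring.

    Worn, sensor-informed minutes are left for the scorer (state column is
    set later and never overwritten here); non-wear minutes will take the
    diary state, and minutes informed by neither source are MISSING.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if wear.shape != (n,) or diary_state.shape != (n,):
        raise ValueError("counts, wear and diary_state must be aligned")
    return pd.DataFrame({
        "minute_index": np.arange(n),
        "clock_min": np.arange(n) % MINUTES_PER_DAY,
        "day_index": np.arange(n) // MINUTES_PER_DAY,
        "activity": counts,
        "wear": np.asarray(wear, dtype=bool),
        "diary_state": np.asarray(diary_state, dtype=np.int8),
    })
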