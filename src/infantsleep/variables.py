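"""The 48 sleep variables: per-day calculators and assessment aggregation.

Conventions (half-open minute grid, extended night clock) come from
:mod:`infantsleep.core`.  Per-day values are computed for the *base*
variables; the 22 cross-day variability slots are sample standard
deviations (n-1 denominator) across valid days, and the three Sleep
Regularity Indices are computed across consecutive valid-day pairs.

Window definitions:

* night window of day ``d``: bedtime(d) .. get-up(d) on the extended clock;
* sleep period: onset(d) .. offset(d)+1 (both landmarks are sleep minutes);
* analysis day of day ``d``: offset(d-1)+1 .. onset(d) — daytime variables
  (Longest Wake, Nap Counter, Sleep after Wake Onset) live here;
* full cycle of day ``d``: offset(d-1)+1 .. offset(d)+1 (Longest Sleep);
* fixed clock windows: 07:00-19:00 of day ``d`` and 19:00(d)-07:00(d+1)
  for the day/night sleep durations, so Day + Night = 24 h exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (MINUTES_PER_DAY, MISSING, SLEEP, WAKE, Family,
                   NightAnchor, extended_to_clock, registry_build)

_REGISTRY = registry_build()

SEVEN_AM = 7 * 60
SEVEN_PM = 19 * 60


@dataclass(frozen=True)
class RunSegment:
    state: int
    start: int
    length: int

    @property
    def end(self) -> int:
        """One past the last minute (half-open)."""
        return self.start + self.length


def runs_in(states: np.ndarray, start: int, end: int) -> list[RunSegment]:
    """Maximal runs of ``states[start:end]``, clipped to the window.

    Start positions are absolute recording minutes.
    """
    start = max(int(start), 0)
    end = min(int(end), len(states))
    if end <= start:
        return []
    seg = np.asarray(states[start:end])
    edges = np.flatnonzero(np.diff(seg)) + 1
    starts = np.r_[0, edges]
    ends = np.r_[edges, seg.size]
    return [RunSegment(int(seg[s]), start + int(s), int(e - s))
            for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# onset / offset landmarks
# ---------------------------------------------------------------------------

def find_onset(states: np.ndarray, bedtime_abs: int, getup_abs: int,
               min_run: int = 10) -> int | None:
    """Sleep onset: absolute minute of the first minute asleep of at least
    ``min_run`` consecutive sleep minutes at or after bedtime.

    If the minute at bedtime is already asleep, the onset is the first
    minute of that ongoing run (walking back before bedtime), with no
    length requirement — the infant was put to bed asleep.
    Returns None when no qualifying run starts before get-up.
    """
    n = len(states)
    b = int(bedtime_abs)
    if 0 <= b < n and states[b] == SLEEP:
        s = b
        while s > 0 and states[s - 1] == SLEEP:
            s -= 1
        return s
    run_start = None
    run_len = 0
    for t in range(max(b, 0), min(int(getup_abs) + 1, n)):
        if states[t] == SLEEP:
            if run_len == 0:
                run_start = t
            run_len += 1
            if run_len >= min_run:
                return run_start
        else:
            run_len = 0
    return None


def find_offset(states: np.ndarray, bedtime_abs: int, getup_abs: int,
                min_run: int = 10) -> int | None:
    """Sleep offset: absolute minute of the last minute asleep of at least
    ``min_run`` consecutive sleep minutes before get-up; if asleep at
    get-up, the last minute of that ongoing run (walking forward).
    """
    n = len(states)
    g = int(getup_abs)
    if 0 <= g < n and states[g] == SLEEP:
        e = g
        while e + 1 < n and states[e + 1] == SLEEP:
            e += 1
        return e
    run_end = None
    run_len = 0
    best = None
    for t in range(max(int(bedtime_abs), 0), min(g, n)):
        if states[t] == SLEEP:
            run_len += 1
            run_end = t
            if run_len >= min_run:
                best = run_end
        else:
            run_len = 0
    return best


def derive_anchor(states: np.ndarray, anchor: NightAnchor, day_index: int
                  ) -> NightAnchor:
    """Fill onset/offset landmarks of a night from scored states."""
    base = day_index * MINUTES_PER_DAY
    b = base + int(round(anchor.bedtime_min))
    g = base + int(round(anchor.getup_min))
    onset = find_onset(states, b, g)
    offset = find_offset(states, b, g)
    anchor.onset_min = None if onset is None else onset - base
    anchor.offset_min = None if offset is None else offset - base
    return anchor


# ---------------------------------------------------------------------------
# per-day calculators
# ---------------------------------------------------------------------------

def night_variables(states: np.ndarray, activity: np.ndarray,
                    anchor: NightAnchor, day_index: int) -> dict[int, float]:
    """Night-window variables (ids 1,3,5,7,9,11,13,15,17,19,21,23,25,27,28).

    Requires a derived onset/offset; returns {} when the night has no
    qualifying sleep run.  All clock outputs follow Table-style reporting:
    bedtime and onset on the extended clock (+1440 past midnight), get-up,
    offset and midsleep as plain clock minutes.
    """
    if anchor.onset_min is None or anchor.offset_min is None:
        return {}
    base = day_index * MINUTES_PER_DAY
    b = base + int(round(anchor.bedtime_min))
    g = base + int(round(anchor.getup_min))
    o = base + int(round(anchor.onset_min))
    f = base + int(round(anchor.offset_min))

    asleep_at_bed = 0 <= b < len(states) and states[b] == SLEEP
    asleep_at_getup = 0 <= g < len(states) and states[g] == SLEEP
    opp_start = o if asleep_at_bed else b
    opp_end = (f + 1) if asleep_at_getup else g
    opportunity = opp_end - opp_start

    period = f + 1 - o
    seg = states[o:f + 1]
    tst = int((seg == SLEEP).sum())
    waso = int((seg == WAKE).sum())

    wake_runs = [r for r in runs_in(states, o, f + 1) if r.state == WAKE]
    # longest nocturnal wake: only wake runs followed by >= 15 min sleep
    longest_wake = 0.0
    sleep_runs_after = {}
    period_runs = runs_in(states, o, f + 1)
    for i, r in enumerate(period_runs):
        if r.state != WAKE:
            continue
        follow = period_runs[i + 1] if i + 1 < len(period_runs) else None
        if follow is not None and follow.state == SLEEP and follow.length >= 15:
            longest_wake = max(longest_wake, r.length)

    act = np.asarray(activity[o:f + 1], dtype=float)
    act_fin = act[np.isfinite(act)]
    act_sd = float(np.std(act_fin, ddof=1)) if act_fin.size > 1 else np.nan
    pct_active = float((act_fin > 0).sum() / period) if period > 0 else np.nan

    out = {
        1: float(anchor.bedtime_min),
        3: extended_to_clock(anchor.getup_min),
        5: float(o - base),
        7: float(max(0, o - b)),
        9: extended_to_clock(f - base),
        # midsleep on a linear minutes-past-midnight axis (can dip slightly
        # negative for pre-midnight midpoints; avoids the wrap at 00:00)
        11: (o + f) / 2.0 - base - MINUTES_PER_DAY,
        13: float(opportunity),
        15: float(period),
        17: float(tst),
        19: 100.0 * tst / opportunity if opportunity > 0 else np.nan,
        21: float(waso),
        23: float(longest_wake),
        25: len(wake_runs) / (period / 60.0) if period > 0 else np.nan,
        27: act_sd,
        28: pct_active,
    }
    return out


def day_variables(states: np.ndarray, prev_offset_abs: int,
                  onset_abs: int, nap_exceed_min: int = 20
                  ) -> dict[int, float]:
    """Daytime variables over the analysis day (ids 30, 32, 34, 36).

    The window runs from the minute after the previous night's offset to
    the current night's onset (exclusive).  Naps are sleep runs strictly
    exceeding ``nap_exceed_min`` minutes.  Longest Sleep (30) is computed
    over the full cycle including the current night.
    """
    start = int(prev_offset_abs) + 1
    end = int(onset_abs)
    if end <= start:
        return {}
    day_runs = runs_in(states, start, end)
    sleep_runs = [r for r in day_runs if r.state == SLEEP]
    wake_runs = [r for r in day_runs if r.state == WAKE]
    naps = [r for r in sleep_runs if r.length > nap_exceed_min]
    longest_wake = max((r.length for r in wake_runs), default=0)

    return {
        32: float(longest_wake),
        34: float(len(naps)),
        36: float(sum(r.length for r in sleep_runs)),
    }


def longest_sleep(states: np.ndarray, cycle_start_abs: int,
                  cycle_end_abs: int) -> float:
    """Longest continuous sleep run in the full cycle (id 30)."""
    cyc = runs_in(states, cycle_start_abs, cycle_end_abs)
    return float(max((r.length for r in cyc if r.state == SLEEP), default=0))


def clock_window_variables(states: np.ndarray, day_index: int
                           ) -> dict[int, float]:
    """Fixed-clock sleep durations for day ``d`` (ids 38, 40, 42, 44).

    Day window 07:00-19:00 of day d, night window 19:00(d)-07:00(d+1),
    24-h window 07:00(d)-07:00(d+1); hence Day + Night = 24 h exactly.
    Requires the full 24-h span inside the recording.
    """
    base = day_index * MINUTES_PER_DAY
    start = base + SEVEN_AM
    mid = base + SEVEN_PM
    end = base + SEVEN_AM + MINUTES_PER_DAY
    if start < 0 or end > len(states):
        return {}
    day_sleep = float((states[start:mid] == SLEEP).sum())
    night_sleep = float((states[mid:end] == SLEEP).sum())
    total = day_sleep + night_sleep
    return {
        38: total,
        40: day_sleep,
        42: night_sleep,
        44: night_sleep / total if total > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# cross-day calculators
# ---------------------------------------------------------------------------

def regularity_index(states: np.ndarray, day_indices: list[int],
                     window: str = "whole") -> float:
    """Sleep Regularity Index over consecutive valid days (ids 46-48).

    For each pair of consecutive listed days, the agreement between the
    sleep/wake state at the same minute-of-day is averaged over the
    window's minutes ('whole' = 0-24 h, 'day' = 07-19 h, 'night' =
    19 h-07 h next day); pair averages are then averaged.  MISSING minutes
    are excluded from numerator and denominator.  Returns NaN with < 2
    days or when no pair has informative minutes.
    """
    if window == "whole":
        lo, hi = 0, MINUTES_PER_DAY
    elif window == "day":
        lo, hi = SEVEN_AM, SEVEN_PM
    elif window == "night":
        lo, hi = SEVEN_PM, SEVEN_AM + MINUTES_PER_DAY
    else:
        raise ValueError(f"unknown window {window!r}")
    days = sorted(day_indices)
    if len(days) < 2:
        return np.nan
    pair_scores = []
    for d1, d2 in zip(days, days[1:]):
        if d2 != d1 + 1:
            continue
        a = states[d1 * MINUTES_PER_DAY + lo: d1 * MINUTES_PER_DAY + hi]
        b = states[d2 * MINUTES_PER_DAY + lo: d2 * MINUTES_PER_DAY + hi]
        m = min(len(a), len(b))
        a, b = np.asarray(a[:m]), np.asarray(b[:m])
        ok = (a != MISSING) & (b != MISSING)
        if ok.sum() == 0:
            continue
        pair_scores.append(float((a[ok] == b[ok]).mean()))
    return float(np.mean(pair_scores)) if pair_scores else np.nan


def variability_variables(daily: pd.DataFrame, min_days: int = 5
                          ) -> dict[int, float]:
    """Cross-day variability slots: sample SD (ddof=1) of each base
    variable across its valid days; NaN below ``min_days`` valid days.
    """
    out: dict[int, float] = {}
    for entry in _REGISTRY:
        if not entry.is_variability:
            continue
        col = entry.base_id
        if col not in daily.columns:
            out[entry.id] = np.nan
            continue
        vals = daily[col].dropna().to_numpy(dtype=float)
        out[entry.id] = (float(np.std(vals, ddof=1))
                         if vals.size >= min_days else np.nan)
    return out


# ---------------------------------------------------------------------------
# assessment-level aggregation
# ---------------------------------------------------------------------------

def aggregate_assessment(daily: pd.DataFrame, sri: dict[int, float],
                         min_days: int = 3, min_days_variability: int = 5
                         ) -> dict[int, float]:
    """Collapse per-day base values into the 48-slot assessment vector.

    ``daily`` has one row per day, columns = base variable ids (NaN where
    the day was invalid for that variable's family).  Base slots are means
    across valid days (NaN below ``min_days``); variability slots are
    cross-day SDs (NaN below ``min_days_variability``); SRI slots come
    precomputed in ``sri``.
    """
    out: dict[int, float] = {}
    for entry in _REGISTRY:
        if entry.id in (46, 47, 48):
            out[entry.id] = sri.get(entry.id, np.nan)
        elif entry.is_variability:
            pass  # filled below
        else:
            vals = daily[entry.id].dropna() if entry.id in daily else pd.Series(dtype=float)
            out[entry.id] = float(vals.mean()) if len(vals) >= min_days else np.nan
    out.update(variability_variables(daily, min_days=min_days_variability))
    return out
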