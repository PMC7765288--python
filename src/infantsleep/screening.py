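"""Per-day validity screening and per-assessment inclusion rules.

A recording day can be invalidated for a *family* of variables without
touching the others: device removal beyond 1 h invalidates partial-day
variables, beyond 3 h entire-day variables, beyond 5 min the
movement-count variables, and a removal intersecting a 30-min window
centred on the reported sleep on-/offset invalidates the clock-time
variables.  Sick days invalidate everything.  A day whose scored states
agree poorly with the 24-h diary is dropped entirely (the agreement
cutoff, default 0.80, is a package stand-in for the original appendix
criterion and is deliberately prominent in the config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (DIARY_SLEEP, DIARY_UNKNOWN, MINUTES_PER_DAY, MISSING,
                   SLEEP, Family, NightAnchor, WAKE)

#: Removal-duration thresholds per family, in minutes.
REMOVAL_THRESHOLDS = {
    Family.PARTIAL_DAY: 60,
    Family.ENTIRE_DAY: 180,
    Family.MOVEMENT_COUNT: 5,
}

#: Half-width of the window centred on reported sleep on-/offset whose
#: intersection with a removal invalidates clock-time variables.
CLOCK_WINDOW_HALF_MIN = 15

DEFAULT_DIARY_FIT_CUTOFF = 0.80


@dataclass
class DayValidity:
    night_id: int
    sick_day: bool = False
    removal_minutes: dict = field(default_factory=dict)  # family -> minutes
    removal_overlaps_onset_window: bool = False
    removal_overlaps_offset_window: bool = False
    diary_fit: float | None = None
    diary_fit_ok: bool = True
    valid_by_family: dict = field(default_factory=dict)

    def valid(self, family: Family) -> bool:
        return bool(self.valid_by_family.get(family, False))


def diary_fit(states: np.ndarray, diary_state: np.ndarray) -> float | None:
    """Fraction of minutes where scored state matches the diary.

    Only minutes with a known diary state and a non-MISSING scored state
    are informative.  Returns None (day kept, caller warns) when the diary
    covers nothing.
    """
    states = np.asarray(states)
    diary_state = np.asarray(diary_state)
    informative = (diary_state != DIARY_UNKNOWN) & (states != MISSING)
    if not informative.any():
        return None
    match = (states[informative] == diary_state[informative])
    return float(match.mean())


def _overlap(wear: np.ndarray, start: float, end: float) -> int:
    """Non-wear minutes within [start, end) clipped to the recording."""
    lo = max(int(np.floor(start)), 0)
    hi = min(int(np.ceil(end)), wear.size)
    if hi <= lo:
        return 0
    return int((~wear[lo:hi]).sum())


def screen_day(wear: np.ndarray, states: np.ndarray,
               diary_state: np.ndarray, anchor: NightAnchor,
               day_index: int, *, sick_day: bool = False,
               prev_offset_abs: float | None = None,
               diary_fit_cutoff: float = DEFAULT_DIARY_FIT_CUTOFF
               ) -> DayValidity:
    """Decide family-level validity for one recording day.

    ``anchor`` landmarks are on the extended clock of ``day_index``;
    absolute recording minutes are ``day_index * 1440 + extended``.
    Removal minutes are counted within each family's own window: the
    night window (bedtime..get-up) for partial-day, movement-count and
    clock-time variables, and the full cycle (previous offset .. this
    offset, falling back to the calendar 24 h around the night) for
    entire-day variables.
    """
    base = day_index * MINUTES_PER_DAY
    bed_abs = base + anchor.bedtime_min
    getup_abs = base + anchor.getup_min

    v = DayValidity(night_id=anchor.night_id, sick_day=sick_day)

    night_removal = _overlap(wear, bed_abs, getup_abs)
    if prev_offset_abs is not None:
        cycle_start = prev_offset_abs
    else:
        cycle_start = max(getup_abs - MINUTES_PER_DAY, 0)
    end_abs = base + (anchor.offset_min if anchor.offset_min is not None
                      else anchor.getup_min)
    cycle_removal = _overlap(wear, cycle_start, end_abs)

    v.removal_minutes = {
        Family.PARTIAL_DAY: night_removal,
        Family.MOVEMENT_COUNT: night_removal,
        Family.ENTIRE_DAY: cycle_removal,
    }

    # clock-time family: removal intersecting the 30-min windows centred
    # on the (reported-or-derived) on-/offset
    onset_abs = base + (anchor.onset_min if anchor.onset_min is not None
                        else anchor.bedtime_min)
    offset_abs = base + (anchor.offset_min if anchor.offset_min is not None
                         else anchor.getup_min)
    v.removal_overlaps_onset_window = _overlap(
        wear, onset_abs - CLOCK_WINDOW_HALF_MIN,
        onset_abs + CLOCK_WINDOW_HALF_MIN) > 0
    v.removal_overlaps_offset_window = _overlap(
        wear, offset_abs - CLOCK_WINDOW_HALF_MIN,
        offset_abs + CLOCK_WINDOW_HALF_MIN) > 0

    lo = max(int(cycle_start), 0)
    hi = min(int(np.ceil(getup_abs)), len(states))
    v.diary_fit = diary_fit(states[lo:hi], diary_state[lo:hi])
    v.diary_fit_ok = (v.diary_fit is None) or (v.diary_fit >= diary_fit_cutoff)

    day_ok = (not sick_day) and v.diary_fit_ok
    v.valid_by_family = {
        Family.PARTIAL_DAY: day_ok and night_removal <= REMOVAL_THRESHOLDS[Family.PARTIAL_DAY],
        Family.MOVEMENT_COUNT: day_ok and night_removal <= REMOVAL_THRESHOLDS[Family.MOVEMENT_COUNT],
        Family.ENTIRE_DAY: day_ok and cycle_removal <= REMOVAL_THRESHOLDS[Family.ENTIRE_DAY],
        Family.CLOCK_TIME: day_ok and not (v.removal_overlaps_onset_window
                                           or v.removal_overlaps_offset_window),
    }
    return v


#: Primary exclusion codes, checked in this order (first match wins).
EXCLUSION_FLAGS = ("timezone_change", "sleep_medication", "medical_problem",
                   "psychological_trauma")


def assessment_inclusion(n_valid_days: int, flags: dict,
                         min_days: int = 3) -> tuple[bool, str | None]:
    """Decide inclusion of one participant-timepoint assessment.

    ``flags`` maps exclusion codes (see EXCLUSION_FLAGS) to booleans.
    Returns (included, primary_reason).  Metadata flags take precedence
    over the too-few-days rule so each excluded assessment carries exactly
    one primary code.
    """
    for code in EXCLUSION_FLAGS:
        if flags.get(code, False):
            return False, code
    if n_valid_days < min_days:
        return False, "too_few_valid_days"
    return True, None
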