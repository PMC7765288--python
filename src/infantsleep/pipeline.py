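"""End-to-end pipeline: minute recordings -> assessment matrix -> composites.

Per recording: score states, derive night anchors (reported bedtime/get-up
with fallback to the first/last diary-reported sleep minute), screen each
day per variable family, compute the per-day variables, and aggregate to
one 48-slot assessment row.  Across the cohort the rows form the wide
assessment matrix fed to imputation and the composite analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variables as svar
from .core import (DIARY_SLEEP, MINUTES_PER_DAY, Family, NightAnchor,
                   registry_build)
from .scoring import ScorerConfig, score_recording
from .screening import (DEFAULT_DIARY_FIT_CUTOFF, assessment_inclusion,
                        screen_day)

_REGISTRY = registry_build()

#: which per-day variable ids belong to which screening family
_FAMILY_OF = {e.id: e.family for e in _REGISTRY if not e.is_variability}


@dataclass
class AssessmentSummary:
    participant: int
    timepoint: int
    exact_age: float
    female: int
    values: dict = field(default_factory=dict)   # variable id -> value/NaN
    n_valid_days: int = 0
    n_valid_days_variability: int = 0
    included: bool = True
    exclusion_reason: str | None = None


def _fallback_anchor(diary_state: np.ndarray, day_index: int
                     ) -> tuple[float | None, float | None]:
    """First/last diary-reported sleep minute of the night window, on the
    extended clock (fallback when the parent left bedtime/get-up blank)."""
    base = day_index * MINUTES_PER_DAY
    lo, hi = base + 1080, min(base + 2160, len(diary_state))
    window = np.asarray(diary_state[lo:hi])
    idx = np.flatnonzero(window == DIARY_SLEEP)
    if idx.size == 0:
        return None, None
    first = float(idx[0] + 1080)
    last = float(idx[-1] + 1080)
    return first, last


def build_anchors(states: np.ndarray, diary_state: np.ndarray,
                  nights: pd.DataFrame) -> list[NightAnchor]:
    """Night anchors from reported times, with diary fallback and derived
    onset/offset landmarks."""
    anchors = []
    for _, row in nights.iterrows():
        d = int(row["night_id"])
        bed, getup = row["reported_bedtime"], row["reported_getup"]
        bed_rep, getup_rep = np.isfinite(bed), np.isfinite(getup)
        fb_first, fb_last = (None, None)
        if not (bed_rep and getup_rep):
            fb_first, fb_last = _fallback_anchor(diary_state, d)
        if not bed_rep:
            bed = fb_first
        if not getup_rep:
            getup = fb_last if fb_last is None else fb_last + 1
        if bed is None or getup is None or not np.isfinite(bed) \
                or not np.isfinite(getup) or bed >= getup:
            continue
        try:
            anchor = NightAnchor(night_id=d, bedtime_min=float(bed),
                                 getup_min=float(getup),
                                 bedtime_reported=bool(bed_rep),
                                 getup_reported=bool(getup_rep))
        except ValueError:
            continue
        anchors.append(svar.derive_anchor(states, anchor, d))
    return anchors


def process_recording(rec, scorer_cfg: ScorerConfig = ScorerConfig(),
                      diary_fit_cutoff: float = DEFAULT_DIARY_FIT_CUTOFF,
                      use_true_states: bool = False
                      ) -> tuple[pd.DataFrame, dict]:
    """Score one recording and compute its per-day variable table.

    Returns (daily table indexed by night with base-variable columns,
    info dict with anchors / validity / SRI values).  With
    ``use_true_states`` the generator's noiseless states bypass the scorer
    (used for ground-truth comparisons).
    """
    minutes = rec.minutes
    if use_true_states:
        scored = minutes.copy()
        scored["state"] = rec.true_states
    else:
        scored = score_recording(minutes, scorer_cfg)
    states = scored["state"].to_numpy()
    activity = minutes["activity"].to_numpy(dtype=float)
    wear = minutes["wear"].to_numpy(dtype=bool)
    diary_state = minutes["diary_state"].to_numpy()

    anchors = build_anchors(states, diary_state, rec.nights)

    rows = []
    validities = {}
    prev_offset_abs = None
    entire_day_valid_days = []
    for anchor in anchors:
        d = anchor.night_id
        base = d * MINUTES_PER_DAY
        validity = screen_day(wear, states, diary_state, anchor, d,
                              sick_day=d in rec.sick_days,
                              prev_offset_abs=prev_offset_abs,
                              diary_fit_cutoff=diary_fit_cutoff)
        validities[d] = validity

        vals: dict[int, float] = {}
        if anchor.onset_min is not None and anchor.offset_min is not None:
            vals.update(svar.night_variables(states, activity, anchor, d))
            onset_abs = base + int(round(anchor.onset_min))
            offset_abs = base + int(round(anchor.offset_min))
            if prev_offset_abs is not None:
                vals.update(svar.day_variables(states, prev_offset_abs,
                                               onset_abs))
                vals[30] = svar.longest_sleep(states, prev_offset_abs + 1,
                                              offset_abs + 1)
                vals.update(svar.clock_window_variables(states, d))
            prev_offset_abs = offset_abs

        # family-level masking
        for vid in list(vals):
            fam = _FAMILY_OF.get(vid)
            if fam is not None and not validity.valid(fam):
                vals[vid] = np.nan
        if validity.valid(Family.ENTIRE_DAY):
            entire_day_valid_days.append(d)
        rows.append({"night_id": d, **vals})

    base_cols = [e.id for e in _REGISTRY
                 if not e.is_variability and e.id not in (46, 47, 48)]
    daily = pd.DataFrame(rows).set_index("night_id") if rows else \
        pd.DataFrame(columns=base_cols)
    daily = daily.reindex(columns=base_cols)

    sri = {46: svar.regularity_index(states, entire_day_valid_days, "whole"),
           47: svar.regularity_index(states, entire_day_valid_days, "day"),
           48: svar.regularity_index(states, entire_day_valid_days, "night")}
    return daily, {"anchors": anchors, "validities": validities, "sri": sri}


def summarize_assessment(rec, meta_row: pd.Series,
                         scorer_cfg: ScorerConfig = ScorerConfig(),
                         min_days: int = 3, min_days_variability: int = 5,
                         use_true_states: bool = False) -> AssessmentSummary:
    """One participant-timepoint: per-day table -> 48-slot summary row."""
    daily, info = process_recording(rec, scorer_cfg,
                                    use_true_states=use_true_states)
    values = svar.aggregate_assessment(daily, info["sri"], min_days=min_days,
                                       min_days_variability=min_days_variability)
    n_valid = int(daily[15].notna().sum()) if 15 in daily else 0
    flags = {k: bool(meta_row.get(k, False))
             for k in ("timezone_change", "sleep_medication",
                       "medical_problem", "psychological_trauma")}
    included, reason = assessment_inclusion(n_valid, flags, min_days=min_days)
    if not included:
        values = {k: np.nan for k in values}
    return AssessmentSummary(
        participant=int(meta_row["participant"]),
        timepoint=int(meta_row["timepoint"]),
        exact_age=float(meta_row["exact_age"]),
        female=int(meta_row["female"]), values=values,
        n_valid_days=n_valid,
        n_valid_days_variability=int(daily[15].notna().sum()) if 15 in daily else 0,
        included=included, exclusion_reason=reason)


def assessment_matrix(cohort, scorer_cfg: ScorerConfig = ScorerConfig(),
                      use_true_states: bool = False) -> pd.DataFrame:
    """Wide assessment matrix: one row per participant-timepoint (present
    in the cohort design, including excluded/dropped assessments as all-NA
    rows, which downstream imputation completes), columns ``vNN_*`` for
    the 48 variables plus ``exact_age`` and ``female``."""
    reg = _REGISTRY
    rows = []
    for _, m in cohort.metadata.iterrows():
        key = (int(m["participant"]), int(m["timepoint"]))
        rec = cohort.recordings.get(key)
        if rec is None:
            values = {vid: np.nan for vid in range(1, 49)}
            row = AssessmentSummary(participant=key[0], timepoint=key[1],
                                    exact_age=float(m["exact_age"]),
                                    female=int(m["female"]), values=values,
                                    included=False,
                                    exclusion_reason="no_recording")
        else:
            row = summarize_assessment(rec, m, scorer_cfg,
                                       use_true_states=use_true_states)
        out = {"participant": row.participant, "timepoint": row.timepoint,
               "exact_age": row.exact_age, "female": row.female,
               "included": row.included, "n_valid_days": row.n_valid_days}
        for vid in range(1, 49):
            out[reg.column(vid)] = row.values.get(vid, np.nan)
        rows.append(out)
    return pd.DataFrame(rows).set_index(["participant", "timepoint"])


def truth_assessment_matrix(cohort) -> pd.DataFrame:
    """Assessment matrix computed from the generator's true states,
    bypassing scorer and screening (every day valid).  Used for recovery
    tests and as the noiseless reference."""
    from .synth import truth_daily_variables

    reg = _REGISTRY
    rows = []
    for _, m in cohort.metadata.iterrows():
        key = (int(m["participant"]), int(m["timepoint"]))
        rec = cohort.recordings.get(key)
        out = {"participant": key[0], "timepoint": key[1],
               "exact_age": float(m["exact_age"]), "female": int(m["female"])}
        if rec is not None:
            daily = truth_daily_variables(rec)
            days = list(daily.index)
            sri = {46: svar.regularity_index(rec.true_states, days, "whole"),
                   47: svar.regularity_index(rec.true_states, days, "day"),
                   48: svar.regularity_index(rec.true_states, days, "night")}
            values = svar.aggregate_assessment(daily.reindex(
                columns=[e.id for e in reg
                         if not e.is_variability and e.id not in (46, 47, 48)]),
                sri)
            for vid in range(1, 49):
                out[reg.column(vid)] = values.get(vid, np.nan)
        else:
            for vid in range(1, 49):
                out[reg.column(vid)] = np.nan
        rows.append(out)
    return pd.DataFrame(rows).set_index(["participant", "timepoint"])
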