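"""Synthetic longitudinal infant-sleep cohort.

The generator emulates a cohort of ~150 infants assessed at 3, 6 and 12
months for ~11 days each.  Five correlated latent factors per
participant-timepoint (activity, variability, day, timing, night) drive a
bout-level generative model: per night, bedtime/get-up and sleep
onset/offset anchors; within the night, wake bouts whose rate and length
scale with the activity factor; during the day, naps whose number and
length scale with the day factor; day-to-day jitter of all anchors scales
with the variability factor.  Per-timepoint target means are calibrated
to the descriptive statistics of the cohort this pipeline operationalizes
(e.g. 3-month mean nap count 4.06, 12-month night-sleep share 0.78).

Activity counts are drawn conditional on state (high-mean gamma bursts in
wake, sparse low bursts in sleep), the 24-h diary is the true state
down-sampled to 15-min majority with reporting noise, and ASQ behavioral
scores are generated from the day factor with participant random
intercepts.  Ground truth (latent factors, true anchors, true per-day
variables) is retained for recovery tests.

All randomness flows from one master seed through per-participant
``numpy`` child streams, so cohorts are byte-identical given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variables as svar
from .core import (DIARY_SLEEP, DIARY_UNKNOWN, DIARY_WAKE, MINUTES_PER_DAY,
                   MISSING, SLEEP, WAKE, NightAnchor)

FACTORS = ("activity", "variability", "day", "timing", "night")

#: Default latent inter-factor correlations.  The four largest values are
#: the reported inter-composite correlations of the reference cohort
#: (activity-day 0.50, timing-variability 0.48, day-night -0.26,
#: night-timing -0.25); the remaining pairs are set to small plausible
#: values of the matching sign structure.
DEFAULT_FACTOR_CORR = pd.DataFrame(
    [[1.00, 0.20, 0.50, 0.10, -0.10],
     [0.20, 1.00, 0.15, 0.48, -0.15],
     [0.50, 0.15, 1.00, 0.10, -0.26],
     [0.10, 0.48, 0.10, 1.00, -0.25],
     [-0.10, -0.15, -0.26, -0.25, 1.00]],
    index=FACTORS, columns=FACTORS)

#: Cross-timepoint persistence of each factor (share of variance carried
#: by a stable participant-level component).
DEFAULT_PERSISTENCE = {"activity": 0.30, "variability": 0.30, "day": 0.30,
                       "timing": 0.60, "night": 0.50}

#: Exact-age windows (months) per assessment.
AGE_WINDOWS = {3: (2.43, 3.39), 6: (5.42, 6.28), 12: (11.47, 12.26)}

#: Per-timepoint calibration targets (minutes / counts / ratios).
#: Keys: bedtime/get-up on the extended clock, within = night-to-night SD,
#: subject = residual between-subject SD beyond the factor effects.
TIMEPOINT_TARGETS = {
    3: dict(bedtime=1273.7, bedtime_within=29.0, bedtime_subject=45.0,
            getup=1912.9, getup_within=33.0, getup_subject=25.0,
            latency=7.8, wake_rate_per_h=0.34, wake_bout_len=18.7,
            nap_count=4.06, nap_len=61.0,
            pct_active=0.30, sleep_burst_mean=240.0, wake_count_mean=500.0),
    6: dict(bedtime=1226.6, bedtime_within=23.0, bedtime_subject=42.0,
            getup=1883.8, getup_within=29.0, getup_subject=25.0,
            latency=11.3, wake_rate_per_h=0.23, wake_bout_len=17.9,
            nap_count=3.20, nap_len=56.0,
            pct_active=0.24, sleep_burst_mean=250.0, wake_count_mean=520.0),
    12: dict(bedtime=1220.8, bedtime_within=19.0, bedtime_subject=32.0,
             getup=1877.9, getup_within=28.0, getup_subject=25.0,
             latency=10.9, wake_rate_per_h=0.14, wake_bout_len=14.9,
             nap_count=2.07, nap_len=73.0,
             pct_active=0.23, sleep_burst_mean=160.0, wake_count_mean=420.0),
}

#: Mean recording length (nights) per timepoint; cohort mean ~10.76 days.
RECORDING_DAYS = {3: (11.13, 1.17), 6: (10.60, 1.91), 12: (10.55, 1.93)}


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 150
    timepoints: tuple[int, ...] = (3, 6, 12)
    factor_corr: pd.DataFrame = field(default_factory=lambda: DEFAULT_FACTOR_CORR)
    persistence: dict = field(default_factory=lambda: dict(DEFAULT_PERSISTENCE))
    #: within-window exact-age slopes on the latent factors, per month
    age_slopes: dict = field(default_factory=lambda: {
        "activity": -0.15, "day": -0.21, "timing": -0.07,
        "variability": -0.08, "night": 0.03})
    sex_effect_activity: float = -0.29  # shift for female infants, factor SD
    #: factor -> anchor effect sizes (minutes per factor SD)
    timing_shift: float = 45.0
    night_shift: float = 25.0
    variability_scale: float = 0.70   # log-scale on night-to-night jitter
    activity_rate_scale: float = 0.30
    activity_len_scale: float = 0.20
    day_count_shift: float = 0.55
    day_len_scale: float = 0.10
    #: diary
    diary_noise: float = 0.05         # misreported 15-min intervals
    diary_anchor_sd: float = 22.0     # reported bed/get-up recall noise (min)
    settle_prob: float = 0.55         # nights with a resettling bout at onset
    diary_anchor_missing: float = 0.05
    #: missingness
    removal_prob_per_day: float = 0.25
    removal_len_mean: float = 45.0
    diary_gap_prob: float = 0.10      # removal not covered by diary
    sick_day_prob: float = 0.02
    dropout_prob: float = 0.02
    flag_probs: dict = field(default_factory=lambda: {
        "timezone_change": 0.004, "sleep_medication": 0.004,
        "medical_problem": 0.004, "psychological_trauma": 0.002})
    #: ASQ generation (Collective score)
    asq_intercept: float = 203.16
    asq_b_day: float = -6.65
    asq_b_age: float = 0.21
    asq_b_female: float = 9.49
    asq_rand_intercept_sd: float = 20.0
    asq_resid_sd: float = 30.0
    seed: int = 42

    def __post_init__(self) -> None:
        c = np.asarray(self.factor_corr, dtype=float)
        if not np.allclose(c, c.T) or np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("factor correlation matrix must be symmetric "
                             "positive-definite")


@dataclass
class Recording:
    participant: int
    timepoint: int
    n_days: int
    minutes: pd.DataFrame      # minute grid incl. activity/wear/diary_state
    nights: pd.DataFrame       # reported bedtime/getup per night
    true_states: np.ndarray
    true_anchors: list[NightAnchor]
    sick_days: set = field(default_factory=set)


@dataclass
class Cohort:
    config: GeneratorConfig
    metadata: pd.DataFrame     # participant, timepoint, exact_age, female, flags
    factors: pd.DataFrame      # latent factor values per assessment
    recordings: dict = field(default_factory=dict)  # (pid, tp) -> Recording
    asq: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# latent layer
# ---------------------------------------------------------------------------

def draw_cohort(cfg: GeneratorConfig, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant metadata and latent factors per assessment.

    Factors are correlated MVN draws split into a stable participant
    component and an occasion component (share set by ``persistence``),
    with a sex shift on the activity factor and small exact-age slopes
    inside each assessment window.
    """
    n = cfg.n_participants
    tps = cfg.timepoints
    chol = np.linalg.cholesky(np.asarray(cfg.factor_corr, dtype=float))
    female = rng.integers(0, 2, size=n)

    stable = rng.standard_normal((n, 5)) @ chol.T
    meta_rows, fac_rows = [], []
    for tp in tps:
        lo, hi = AGE_WINDOWS[tp]
        ages = rng.uniform(lo, hi, size=n)
        occasion = rng.standard_normal((n, 5)) @ chol.T
        w = np.array([cfg.persistence[f] for f in FACTORS])
        fac = np.sqrt(w) * stable + np.sqrt(1 - w) * occasion
        fac[:, FACTORS.index("activity")] += cfg.sex_effect_activity * female
        center = (lo + hi) / 2
        for j, f in enumerate(FACTORS):
            fac[:, j] += cfg.age_slopes.get(f, 0.0) * (ages - center)
        for i in range(n):
            meta_rows.append({"participant": i, "timepoint": tp,
                              "exact_age": ages[i], "female": int(female[i]),
                              **{k: False for k in cfg.flag_probs}})
            fac_rows.append({"participant": i, "timepoint": tp,
                             **dict(zip(FACTORS, fac[i]))})
    return pd.DataFrame(meta_rows), pd.DataFrame(fac_rows)


# ---------------------------------------------------------------------------
# minute-level realization
# ---------------------------------------------------------------------------

def _place_bouts(rng, lo: int, hi: int, n: int, lengths: np.ndarray,
                 margin: int) -> list[tuple[int, int]]:
    """Place n non-overlapping bouts inside [lo, hi) with a wake margin."""
    placed = []
    for length in lengths[:n]:
        length = int(length)
        for _ in range(50):
            if hi - lo - length <= 0:
                break
            s = int(rng.integers(lo, hi - length))
            if all(s + length + margin <= a or b + margin <= s
                   for a, b in placed):
                placed.append((s, s + length))
                break
    return sorted(placed)


def realize_days(factors_row: pd.Series, tp: int, n_days: int,
                 cfg: GeneratorConfig, rng: np.random.Generator,
                 with_activity: bool = True) -> Recording:
    """Realize one assessment: true states, anchors, counts and diary.

    The recording covers ``n_days + 1`` calendar days; the stretch before
    the first evening (device not yet worn) and after the last morning
    get-up are MISSING, mirroring a protocol where the sensor goes on
    before bedtime of day 0 and comes off after get-up of the last day.
    """
    t = TIMEPOINT_TARGETS[tp]
    f = {k: float(factors_row[k]) for k in FACTORS}
    n_min = (n_days + 1) * MINUTES_PER_DAY
    states = np.full(n_min, WAKE, dtype=np.int8)

    # subject-level anchor means: a common schedule preference shifts the
    # evening and morning anchors together; the residual evening/morning
    # components are kept small so the latent factors dominate the
    # between-variable correlation structure.
    pref = rng.normal(0, 0.75 * t["bedtime_subject"])
    bed_subj = (t["bedtime"] + cfg.timing_shift * f["timing"]
                - cfg.night_shift * f["night"]
                + pref + rng.normal(0, 0.35 * t["bedtime_subject"]))
    getup_subj = (t["getup"] + cfg.timing_shift * f["timing"]
                  + cfg.night_shift * f["night"]
                  + pref + rng.normal(0, 0.45 * t["getup_subject"]))
    lat_subj = max(2.0, t["latency"] * np.exp(rng.normal(0, 0.4)))
    jitter = np.exp(cfg.variability_scale * f["variability"])
    rate_subj = (t["wake_rate_per_h"]
                 * np.exp(cfg.activity_rate_scale * f["activity"]
                          + rng.normal(0, 0.06)))
    blen_subj = t["wake_bout_len"] * np.exp(
        cfg.activity_len_scale * f["activity"] + rng.normal(0, 0.05))
    nap_subj = max(0.2, t["nap_count"] + cfg.day_count_shift * f["day"]
                   + rng.normal(0, 0.2))
    naplen_subj = t["nap_len"] * np.exp(cfg.day_len_scale * f["day"]
                                        + rng.normal(0, 0.08))
    pct_active_subj = np.clip(t["pct_active"] + 0.04 * f["activity"]
                              + rng.normal(0, 0.01), 0.05, 0.6)

    anchors: list[NightAnchor] = []
    onsets, offsets = [], []
    for d in range(n_days):
        # night-level common component: household schedule shifts the
        # whole night, partially shared between bedtime and get-up
        q = rng.standard_normal()
        bed = bed_subj + (0.35 * q + 0.94 * rng.standard_normal()) \
            * t["bedtime_within"] * jitter
        bed = float(np.clip(bed, 1120, 1650))
        getup = getup_subj + (0.35 * q + 0.94 * rng.standard_normal()) \
            * t["getup_within"] * jitter
        getup = float(np.clip(getup, max(bed + 420, 1740), 2150))
        latency = min(rng.gamma(1.2, lat_subj / 1.2), 100.0)
        onset = bed + latency
        offset = max(getup - rng.exponential(2.0), onset + 240)
        offset = min(offset, getup + 30)

        base = d * MINUTES_PER_DAY
        o, fz = base + int(round(onset)), base + int(round(offset))
        states[o:fz + 1] = SLEEP

        # resettling: many infants surface briefly a few minutes after
        # falling asleep, so the consolidated (>=10 min) onset lands after
        # the resettle rather than at first sleep
        if rng.random() < cfg.settle_prob:
            s = o + int(rng.integers(2, 9))
            ln = max(3, int(round(rng.lognormal(np.log(18), 0.5))))
            if s + ln < fz - 30:
                states[s:s + ln] = WAKE

        # nocturnal wake bouts; the activity factor drives not only the
        # mean fragmentation but also its night-to-night dispersion
        hours = (fz - o) / 60.0
        act_disp = max(0.1, 0.45 + 0.20 * f["activity"])
        night_mult = np.exp(act_disp * rng.standard_normal()
                            - act_disp ** 2 / 2)
        n_bouts = rng.poisson(rate_subj * night_mult * hours)
        lengths = np.maximum(2, np.rint(rng.lognormal(
            np.log(blen_subj) - 0.18, 0.6, size=max(n_bouts, 1)))).astype(int)
        for s, e in _place_bouts(rng, o + 12, fz - 12, n_bouts, lengths, 8):
            states[s:e] = WAKE

        anchors.append(NightAnchor(night_id=d, bedtime_min=bed,
                                   getup_min=getup))
        onsets.append(o)
        offsets.append(fz)

    # naps within each daytime window (offset d-1 .. onset d); day 0 uses
    # an early-afternoon window before the first bedtime
    for d in range(n_days):
        if d == 0:
            lo = int(18.0 * 60)  # device goes on ~18:00 of day 0
            window_lo = lo + 5
        else:
            window_lo = offsets[d - 1] + 30
        window_hi = onsets[d] - 30
        if window_hi - window_lo < 60:
            continue
        mean_naps = nap_subj if d else nap_subj * min(
            1.0, (window_hi - window_lo) / 700.0)
        n_naps = max(0, int(round(rng.normal(mean_naps, 0.9))))
        lengths = np.maximum(
            22, rng.lognormal(np.log(naplen_subj) - 0.10, 0.45,
                              size=max(n_naps, 1))).astype(int)
        for s, e in _place_bouts(rng, window_lo, window_hi, n_naps,
                                 lengths, 20):
            states[s:e] = SLEEP

    # not-yet-worn head and post-get-up tail
    head_end = int(18.0 * 60)
    states[:head_end] = MISSING
    tail_start = max(offsets[-1] + 1,
                     (n_days - 1) * MINUTES_PER_DAY
                     + int(round(anchors[-1].getup_min)))
    states[tail_start:] = MISSING

    # activity counts conditional on state
    activity = np.full(n_min, np.nan)
    if with_activity:
        wake_mask = states == WAKE
        sleep_mask = states == SLEEP
        activity[wake_mask] = rng.gamma(3.0, t["wake_count_mean"] / 3.0,
                                        size=wake_mask.sum())
        burst = rng.random(sleep_mask.sum()) < pct_active_subj
        s_act = np.zeros(sleep_mask.sum())
        scale = (t["sleep_burst_mean"]
                 * np.exp(0.25 * f["activity"])) / 1.5
        s_act[burst] = rng.gamma(1.5, scale, size=int(burst.sum()))
        activity[sleep_mask] = s_act

    # diary: 15-min majority of true states + reporting noise
    n_int = n_min // 15
    blocks = states[: n_int * 15].reshape(n_int, 15)
    sleep_frac = (blocks == SLEEP).mean(axis=1)
    known = (blocks != MISSING).mean(axis=1) > 0.5
    diary_state = np.full(n_int, DIARY_UNKNOWN, dtype=np.int8)
    diary_state[known & (sleep_frac >= 0.5)] = DIARY_SLEEP
    diary_state[known & (sleep_frac < 0.5)] = DIARY_WAKE
    flip = known & (rng.random(n_int) < cfg.diary_noise)
    diary_state[flip] = np.where(diary_state[flip] == DIARY_SLEEP,
                                 DIARY_WAKE, DIARY_SLEEP)
    diary_min = np.repeat(diary_state, 15)
    diary_min = np.r_[diary_min, np.full(n_min - diary_min.size,
                                         DIARY_UNKNOWN, dtype=np.int8)]

    # reported anchors: parents report to a 5-min grid with recall noise;
    # households with irregular schedules also report less precisely
    night_rows = []
    anchor_sd = cfg.diary_anchor_sd * jitter
    for a in anchors:
        rep_bed = 5 * round((a.bedtime_min + rng.normal(0, anchor_sd)) / 5)
        rep_get = 5 * round((a.getup_min + rng.normal(0, anchor_sd)) / 5)
        if rng.random() < cfg.diary_anchor_missing:
            rep_bed = np.nan
        if rng.random() < cfg.diary_anchor_missing:
            rep_get = np.nan
        night_rows.append({"night_id": a.night_id,
                           "reported_bedtime": rep_bed,
                           "reported_getup": rep_get})

    wear = states != MISSING
    minutes = pd.DataFrame({
        "minute_index": np.arange(n_min),
        "clock_min": np.arange(n_min) % MINUTES_PER_DAY,
        "day_index": np.arange(n_min) // MINUTES_PER_DAY,
        "activity": activity,
        "wear": wear,
        "diary_state": diary_min,
        "external_movement": rng.random(n_min) < 0.01,
    })

    # true landmarks re-derived from the realized states (the resettle
    # bout can move the consolidated onset after first sleep)
    from .variables import find_offset, find_onset
    for a in anchors:
        base = a.night_id * MINUTES_PER_DAY
        b_abs = base + int(round(a.bedtime_min))
        g_abs = base + int(round(a.getup_min))
        on = find_onset(states, b_abs, g_abs)
        off = find_offset(states, b_abs, g_abs)
        a.onset_min = None if on is None else on - base
        a.offset_min = None if off is None else off - base

    return Recording(participant=int(factors_row["participant"]),
                     timepoint=tp, n_days=n_days, minutes=minutes,
                     nights=pd.DataFrame(night_rows), true_states=states,
                     true_anchors=anchors)


def inject_missingness(rec: Recording, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> Recording:
    """Add device-removal gaps, diary holes and sick-day flags in place."""
    minutes = rec.minutes
    n_min = len(minutes)
    wear = minutes["wear"].to_numpy().copy()
    activity = minutes["activity"].to_numpy().copy()
    diary = minutes["diary_state"].to_numpy().copy()
    for d in range(rec.n_days):
        if rng.random() >= cfg.removal_prob_per_day:
            continue
        start = int(d * MINUTES_PER_DAY
                    + rng.integers(6 * 60, 22 * 60))
        length = int(np.clip(rng.lognormal(np.log(cfg.removal_len_mean),
                                           0.8), 8, 360))
        end = min(start + length, n_min)
        wear[start:end] = False
        activity[start:end] = np.nan
        if rng.random() < cfg.diary_gap_prob:
            diary[start:end] = DIARY_UNKNOWN
    minutes["wear"] = wear
    minutes["activity"] = activity
    minutes["diary_state"] = diary
    rec.sick_days = {int(d) for d in range(rec.n_days)
                     if rng.random() < cfg.sick_day_prob}
    return rec


def attach_asq(metadata: pd.DataFrame, factors: pd.DataFrame,
               cfg: GeneratorConfig, rng: np.random.Generator
               ) -> pd.DataFrame:
    """ASQ tables: Collective driven by the day factor; subscales null."""
    merged = metadata.merge(factors, on=["participant", "timepoint"])
    pids = merged["participant"].unique()
    u = dict(zip(pids, rng.normal(0, cfg.asq_rand_intercept_sd,
                                  size=pids.size)))
    ui = merged["participant"].map(u).to_numpy()
    collective = (cfg.asq_intercept
                  + cfg.asq_b_day * merged["day"].to_numpy()
                  + cfg.asq_b_age * merged["exact_age"].to_numpy()
                  + cfg.asq_b_female * merged["female"].to_numpy()
                  + ui + rng.normal(0, cfg.asq_resid_sd, len(merged)))
    ps = (42.17 - 0.37 * merged["exact_age"].to_numpy()
          + 1.76 * merged["female"].to_numpy()
          + 0.35 * ui + rng.normal(0, 9.0, len(merged)))
    gm = (38.82 + 0.14 * merged["exact_age"].to_numpy()
          + 0.90 * merged["female"].to_numpy()
          + 0.35 * ui + rng.normal(0, 10.0, len(merged)))
    return pd.DataFrame({
        "participant": merged["participant"],
        "timepoint": merged["timepoint"],
        "asq_collective": collective,
        "asq_personal_social": ps,
        "asq_gross_motor": gm,
    })


def generate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None, with_activity: bool = True,
                    with_missingness: bool = True) -> Cohort:
    """Full cohort: metadata, factors, minute recordings and ASQ tables."""
    cfg = cfg or GeneratorConfig()
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng = np.random.default_rng(ss)
    metadata, factors = draw_cohort(cfg, rng)

    # dropout and metadata exclusion flags
    drop = rng.random(len(metadata)) < cfg.dropout_prob
    for flag, p in cfg.flag_probs.items():
        metadata[flag] = rng.random(len(metadata)) < p
    metadata["dropped"] = drop

    cohort = Cohort(config=cfg, metadata=metadata, factors=factors)
    child_seeds = ss.spawn(len(metadata))
    fac_idx = factors.set_index(["participant", "timepoint"])
    for row_i, (_, m) in enumerate(metadata.iterrows()):
        if m["dropped"]:
            continue
        pid, tp = int(m["participant"]), int(m["timepoint"])
        sub_rng = np.random.default_rng(child_seeds[row_i])
        mu, sd = RECORDING_DAYS[tp]
        n_days = int(np.clip(round(sub_rng.normal(mu, sd)), 7, 14))
        frow = fac_idx.loc[(pid, tp)].copy()
        frow["participant"] = pid
        rec = realize_days(frow, tp, n_days, cfg, sub_rng,
                           with_activity=with_activity)
        if with_missingness:
            rec = inject_missingness(rec, cfg, sub_rng)
        cohort.recordings[(pid, tp)] = rec
    cohort.asq = attach_asq(metadata, factors, cfg, rng)
    return cohort


# ---------------------------------------------------------------------------
# ground-truth variable tables (no scoring noise / no missingness)
# ---------------------------------------------------------------------------

def truth_daily_variables(rec: Recording) -> pd.DataFrame:
    """Per-day base variables computed from the generator's true states."""
    states = rec.true_states
    activity = rec.minutes["activity"].to_numpy(dtype=float)
    has_activity = np.isfinite(activity).any()
    rows = []
    prev_offset_abs = None
    for a in rec.true_anchors:
        d = a.night_id
        base = d * MINUTES_PER_DAY
        vals = svar.night_variables(states, activity, a, d)
        if not has_activity:
            vals.pop(27, None)
            vals.pop(28, None)
        if prev_offset_abs is not None and a.onset_min is not None:
            vals.update(svar.day_variables(states, prev_offset_abs,
                                           base + int(round(a.onset_min))))
            vals[30] = svar.longest_sleep(states, prev_offset_abs + 1,
                                          base + int(round(a.offset_min)) + 1)
            vals.update(svar.clock_window_variables(states, d))
        rows.append({"night_id": d, **vals})
        if a.offset_min is not None:
            prev_offset_abs = base + int(round(a.offset_min))
    return pd.DataFrame(rows).set_index("night_id")
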