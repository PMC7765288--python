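"""Per-day variable calculators vs independent brute-force oracles.

The oracle functions below re-derive every quantity by naive scanning of
the minute sequence, with no shared code with the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from infantsleep.core import (MINUTES_PER_DAY, MISSING, NightAnchor, SLEEP,
                              WAKE)
from infantsleep.variables import (aggregate_assessment, clock_window_variables,
                                   day_variables, find_offset, find_onset,
                                   longest_sleep, night_variables,
                                   regularity_index, runs_in,
                                   variability_variables)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_runs(states, start, end):
    out = []
    cur = None
    for t in range(max(start, 0), min(end, len(states))):
        s = states[t]
        if cur is None or s != cur[0]:
            cur = [s, t, 0]
            out.append(cur)
        cur[2] += 1
    return [(s, a, n) for s, a, n in out]


def oracle_onset(states, bed, getup, min_run=10):
    if 0 <= bed < len(states) and states[bed] == SLEEP:
        t = bed
        while t > 0 and states[t - 1] == SLEEP:
            t -= 1
        return t
    for t in range(max(bed, 0), min(getup + 1, len(states))):
        if all(states[t + i] == SLEEP for i in range(min_run)
               if t + i < len(states)) and t + min_run <= len(states):
            if all(states[t + i] == SLEEP for i in range(min_run)):
                return t
    return None


def oracle_offset(states, bed, getup, min_run=10):
    if 0 <= getup < len(states) and states[getup] == SLEEP:
        t = getup
        while t + 1 < len(states) and states[t + 1] == SLEEP:
            t += 1
        return t
    best = None
    for t in range(max(bed, 0), min(getup, len(states))):
        if t - min_run + 1 >= 0 and all(
                states[t - i] == SLEEP for i in range(min_run)):
            best = t
    return best


def oracle_longest_run(states, start, end, which):
    best = cur = 0
    for t in range(max(start, 0), min(end, len(states))):
        if states[t] == which:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


# ---------------------------------------------------------------------------
# landmark examples
# ---------------------------------------------------------------------------

def seq(*pairs):
    return np.concatenate([np.full(n, s, dtype=np.int8) for s, n in pairs])


class TestOnsetOffset:
    def test_onset_first_long_run_after_bedtime(self):
        states = seq((WAKE, 1210), (SLEEP, 200), (WAKE, 100))
        assert find_onset(states, 1200, 1500) == 1210

    def test_onset_walks_back_when_asleep_at_bedtime(self):
        states = seq((WAKE, 1195), (SLEEP, 300))
        assert find_onset(states, 1200, 1490) == 1195

    def test_onset_skips_runs_shorter_than_ten(self):
        states = seq((WAKE, 1200), (SLEEP, 8), (WAKE, 5), (SLEEP, 30),
                     (WAKE, 60))
        assert find_onset(states, 1195, 1300) == 1213

    def test_offset_last_long_run_before_getup(self):
        states = seq((SLEEP, 446), (WAKE, 100))
        assert find_offset(states, 0, 460) == 445

    def test_offset_walks_forward_when_asleep_at_getup(self):
        states = seq((SLEEP, 473), (WAKE, 30))
        assert find_offset(states, 0, 460) == 472

    def test_offset_ignores_short_final_runs(self):
        states = seq((SLEEP, 400), (WAKE, 31), (SLEEP, 9), (WAKE, 20))
        assert find_offset(states, 0, 459) == 399


# ---------------------------------------------------------------------------
# night variables
# ---------------------------------------------------------------------------

class TestNightVariables:
    def build(self, states):
        anchor = NightAnchor(night_id=0, bedtime_min=1200.0, getup_min=1900.0)
        anchor.onset_min = find_onset(states, 1200, 1900)
        anchor.offset_min = find_offset(states, 1200, 1900)
        activity = np.zeros(len(states))
        return night_variables(states, activity, anchor, 0)

    def test_efficiency_from_printed_formula(self):
        # 600-min opportunity, 540 asleep inside it
        states = seq((WAKE, 1200), (SLEEP, 300), (WAKE, 60), (SLEEP, 240),
                     (WAKE, 1000))
        vals = self.build(states)
        assert vals[13] == 700.0   # bed 1200 .. getup 1900
        assert vals[17] == 540.0
        assert vals[21] == pytest.approx(vals[15] - vals[17])
        assert vals[19] == pytest.approx(100 * 540 / 700)

    def test_latency_clamped_to_zero_when_asleep_before_bedtime(self):
        states = seq((WAKE, 1190), (SLEEP, 600), (WAKE, 400))
        vals = self.build(states)
        assert vals[5] == 1190.0
        assert vals[7] == 0.0

    def test_longest_wake_requires_15min_sleep_after(self):
        # 25-min bout followed by 30 min sleep qualifies; a later 40-min
        # bout followed by only 10 min sleep does not
        states = seq((WAKE, 1200), (SLEEP, 100), (WAKE, 25), (SLEEP, 30),
                     (WAKE, 40), (SLEEP, 10), (WAKE, 20), (SLEEP, 100),
                     (WAKE, 500))
        vals = self.build(states)
        assert vals[23] == 25.0

    def test_tst_plus_waso_equals_period(self):
        rng = np.random.default_rng(5)
        states = seq((WAKE, 1200), (SLEEP, 20))
        tail = rng.choice([SLEEP, WAKE], size=640, p=[0.8, 0.2]).astype(np.int8)
        states = np.r_[states, tail, np.full(300, WAKE, dtype=np.int8)]
        vals = self.build(states)
        assert vals[17] + vals[21] == vals[15]


class TestDayVariables:
    def test_nap_counting_and_day_sleep(self):
        # daytime window with naps of 25, 18 and 45 minutes
        states = seq((WAKE, 100), (SLEEP, 25), (WAKE, 50), (SLEEP, 18),
                     (WAKE, 50), (SLEEP, 45), (WAKE, 100))
        vals = day_variables(states, prev_offset_abs=-1, onset_abs=len(states))
        assert vals[34] == 2.0         # strict 'exceeding 20 min'
        assert vals[36] == 88.0

    def test_run_of_exactly_20_not_a_nap(self):
        states = seq((WAKE, 50), (SLEEP, 20), (WAKE, 50))
        vals = day_variables(states, -1, len(states))
        assert vals[34] == 0.0

    def test_no_daytime_sleep_longest_wake_is_window(self):
        states = seq((WAKE, 300),)
        vals = day_variables(states, -1, 300)
        assert vals[34] == 0.0
        assert vals[32] == 300.0

    def test_longest_sleep_spans_cycle(self):
        states = seq((WAKE, 60), (SLEEP, 45), (WAKE, 60), (SLEEP, 200),
                     (WAKE, 30))
        assert longest_sleep(states, 0, len(states)) == 200.0


class TestClockWindows:
    def test_all_day_sleep_splits_evenly(self):
        states = np.full(3 * MINUTES_PER_DAY, SLEEP, dtype=np.int8)
        vals = clock_window_variables(states, 1)
        assert vals[40] == 720.0
        assert vals[42] == 720.0
        assert vals[38] == 1440.0
        assert vals[44] == 0.5

    def test_evening_to_morning_sleep_is_night_only(self):
        states = np.full(3 * MINUTES_PER_DAY, WAKE, dtype=np.int8)
        # sleep 20:00 day 1 to 06:00 day 2
        states[MINUTES_PER_DAY + 20 * 60: 2 * MINUTES_PER_DAY + 6 * 60] = SLEEP
        vals = clock_window_variables(states, 1)
        assert vals[40] == 0.0
        assert vals[42] == 600.0
        assert vals[44] == 1.0

    def test_day_plus_night_equals_24h(self):
        rng = np.random.default_rng(7)
        states = rng.choice([SLEEP, WAKE], size=3 * MINUTES_PER_DAY
                            ).astype(np.int8)
        vals = clock_window_variables(states, 1)
        assert vals[40] + vals[42] == vals[38]


class TestRegularity:
    def test_identical_days_give_one(self):
        day = np.r_[np.full(480, SLEEP, np.int8), np.full(960, WAKE, np.int8)]
        states = np.tile(day, 3)
        assert regularity_index(states, [0, 1, 2], "whole") == 1.0

    def test_complementary_days_give_zero(self):
        day = np.r_[np.full(720, SLEEP, np.int8), np.full(720, WAKE, np.int8)]
        states = np.r_[day, day[::-1]]
        assert regularity_index(states, [0, 1], "whole") == 0.0

    def test_partial_agreement_ratio(self):
        day1 = np.full(1440, SLEEP, dtype=np.int8)
        day2 = day1.copy()
        day2[:360] = WAKE   # disagree on 360 of 1440
        states = np.r_[day1, day2]
        assert regularity_index(states, [0, 1], "whole") == pytest.approx(0.75)

    def test_single_day_is_nan(self):
        states = np.full(1440, SLEEP, dtype=np.int8)
        assert np.isnan(regularity_index(states, [0], "whole"))

    def test_missing_minutes_excluded(self):
        day1 = np.full(1440, SLEEP, dtype=np.int8)
        day2 = day1.copy()
        day2[:720] = MISSING
        states = np.r_[day1, day2]
        assert regularity_index(states, [0, 1], "whole") == 1.0

    def test_adding_identical_day_never_decreases(self):
        day1 = np.full(1440, SLEEP, dtype=np.int8)
        day2 = day1.copy(); day2[:100] = WAKE
        two = regularity_index(np.r_[day1, day2], [0, 1], "whole")
        three = regularity_index(np.r_[day1, day2, day2], [0, 1, 2], "whole")
        assert three >= two


class TestVariability:
    def _daily(self, bedtimes):
        return pd.DataFrame({1: bedtimes})

    def test_constant_bedtime_gives_zero(self):
        out = variability_variables(self._daily([1200.0] * 6))
        assert out[2] == 0.0

    def test_sample_sd_with_n_minus_1(self):
        out = variability_variables(self._daily([1200.0, 1210, 1220, 1200,
                                                 1210, 1220]))
        assert out[2] == pytest.approx(np.std([1200, 1210, 1220] * 2, ddof=1))

    def test_four_days_is_nan(self):
        out = variability_variables(self._daily([1200.0, 1210, 1220, 1230]))
        assert np.isnan(out[2])


class TestAggregation:
    def test_means_over_valid_days_only(self):
        daily = pd.DataFrame({17: [600.0, 660.0, np.nan, 620.0],
                              21: [50.0, np.nan, np.nan, np.nan]})
        daily = daily.reindex(columns=range(1, 46))
        out = aggregate_assessment(daily, sri={}, min_days=3)
        assert out[17] == pytest.approx((600 + 660 + 620) / 3)
        assert np.isnan(out[21])  # only one valid day

    def test_48_slots_always_present(self):
        daily = pd.DataFrame({17: [600.0] * 5}).reindex(columns=range(1, 46))
        out = aggregate_assessment(daily, sri={46: 0.8, 47: 0.7, 48: 0.9})
        assert set(out) == set(range(1, 49))


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("trial_seed", range(25))
    def test_calculators_match_brute_force(self, trial_seed):
        """40 random 2-day toy series per seed: every run/landmark-based
        calculator must agree exactly with naive scanning."""
        rng = np.random.default_rng(trial_seed)
        for _ in range(40):
            n = 2 * MINUTES_PER_DAY
            # blocky random states so runs have realistic lengths
            states = np.repeat(
                rng.choice([SLEEP, WAKE], size=n // 16, p=[0.55, 0.45]),
                16).astype(np.int8)
            bed = int(rng.integers(1150, 1350))
            getup = int(rng.integers(1750, 2000))

            on = find_onset(states, bed, getup)
            off = find_offset(states, bed, getup)
            assert on == oracle_onset(states, bed, getup)
            assert off == oracle_offset(states, bed, getup)
            if on is None or off is None:
                continue

            anchor = NightAnchor(0, float(bed), float(getup),
                                 onset_min=float(on), offset_min=float(off))
            vals = night_variables(states, np.zeros(n), anchor, 0)
            seg = states[on:off + 1]
            assert vals[17] == sum(1 for s in seg if s == SLEEP)
            assert vals[21] == sum(1 for s in seg if s == WAKE)
            assert vals[15] == off - on + 1

            w = int(rng.integers(200, 900))
            dv = day_variables(states, w, bed)
            if dv:
                runs = oracle_runs(states, w + 1, bed)
                assert dv[34] == sum(1 for s, _a, ln in runs
                                     if s == SLEEP and ln > 20)
                assert dv[36] == sum(ln for s, _a, ln in runs if s == SLEEP)
                assert dv[32] == oracle_longest_run(states, w + 1, bed, WAKE)
            assert longest_sleep(states, 0, n) == \
                oracle_longest_run(states, 0, n, SLEEP)
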