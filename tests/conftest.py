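import numpy as np
import pandas as pd
import pytest

from infantsleep.core import (DIARY_SLEEP, DIARY_UNKNOWN, DIARY_WAKE,
                              MINUTES_PER_DAY, MISSING, SLEEP, WAKE)


def make_states(segments):
    """Build a state array from (state, length) segments."""
    return np.concatenate([np.full(n, s, dtype=np.int8) for s, n in segments])


@pytest.fixture(scope="session")
def two_night_recording():
    """A hand-built 3-day recording with two clean nights.

    Night 0: bedtime 21:00 (1260), sleep 21:10-07:00 next day with a
    20-min wake bout at 02:00; get-up 07:10 (extended 1870).
    Day 1: naps 10:00-10:45 and 14:00-14:25.
    Night 1: bedtime 21:30 (1290), sleep 21:35-06:30; get-up 06:40.
    """
    n = 3 * MINUTES_PER_DAY
    states = np.full(n, WAKE, dtype=np.int8)
    states[:18 * 60] = MISSING  # device goes on in the evening of day 0
    states[1270:1440 + 7 * 60] = SLEEP          # night 0
    states[1440 + 120:1440 + 140] = WAKE        # 02:00 bout, 20 min
    states[1440 + 10 * 60:1440 + 10 * 60 + 45] = SLEEP   # nap 1
    states[1440 + 14 * 60:1440 + 14 * 60 + 25] = SLEEP   # nap 2
    states[1440 + 1295:2 * 1440 + 6 * 60 + 30] = SLEEP   # night 1
    states[2 * 1440 + 7 * 60:] = MISSING
    nights = pd.DataFrame({
        "night_id": [0, 1],
        "reported_bedtime": [1260.0, 1295.0],
        "reported_getup": [1870.0, 1840.0],
    })
    return states, nights


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across tests (12 participants)."""
    from infantsleep.synth import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(n_participants=12, seed=123)
    return generate_cohort(cfg)
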