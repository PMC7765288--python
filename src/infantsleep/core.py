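"""Core domain model: minute grid conventions, night anchors, and the
48-variable registry.

Time conventions
----------------
All clock times are integer (or fractional) minutes since midnight of the
*calendar day a night belongs to*.  Evening events that slip past midnight
(a 00:30 bedtime) are mapped onto an "extended clock" by adding 1440, so
that every night's event sequence (bedtime < onset < offset < get-up) is
monotone on a single axis.  Morning events of the following day (get-up
time, sleep offset) always live at ``clock + 1440`` on that axis.

The minute grid is half-open: minute ``t`` covers ``[t, t+1)``; a "minute
asleep" is a minute whose scored state is SLEEP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

MINUTES_PER_DAY = 1440

#: Sleep/wake state codes used on the minute grid.
WAKE = 0
SLEEP = 1
MISSING = -1

#: Diary state codes (per 15-min interval, broadcast to minutes).
DIARY_WAKE = 0
DIARY_SLEEP = 1
DIARY_UNKNOWN = -1

#: Evening clock times strictly before this cutoff (04:00) are treated as
#: past-midnight events and mapped to clock + 1440.  No infant bedtime in
#: the cohorts this package targets plausibly precedes 04:00 as a *morning*
#: event, and none follows noon as a morning get-up.
EVENING_CUTOFF_MIN = 240


class Family(str, Enum):
    """Screening family of a sleep variable.

    Day-level validity is decided per family: a removal of the actigraph
    invalidates partial-day variables beyond 1 h, entire-day variables
    beyond 3 h, movement-count variables beyond 5 min, and clock-time
    variables when it intersects a 30-min window centred on the reported
    sleep on-/offset.
    """

    PARTIAL_DAY = "partial-day"
    ENTIRE_DAY = "entire-day"
    MOVEMENT_COUNT = "movement-count"
    CLOCK_TIME = "clock-time"


class Window(str, Enum):
    """Analysis window a variable is computed over."""

    NIGHT = "night"          # sleep-opportunity / sleep-period window
    DAY = "day"              # sleep offset (night d-1) -> sleep onset (night d)
    FULL_24H = "24h"
    CLOCK_DAY = "7am-7pm"
    CLOCK_NIGHT = "7pm-7am"


def clock_to_extended(clock_min: float, next_day: bool = False,
                      evening_cutoff: float = EVENING_CUTOFF_MIN) -> float:
    """Map a clock time (minutes since midnight, in [0, 1440)) onto the
    extended night axis.

    Evening events before ``evening_cutoff`` are assumed to have slipped
    past midnight and get +1440; morning events of the following day
    (``next_day=True``) always get +1440.

    >>> clock_to_extended(1274)   # 21:14
    1274
    >>> clock_to_extended(79)     # 01:19, past midnight
    1519
    >>> clock_to_extended(0)      # exactly midnight
    1440
    """
    if not 0 <= clock_min < MINUTES_PER_DAY:
        raise ValueError(f"clock_min must be in [0, 1440), got {clock_min}")
    if next_day or clock_min < evening_cutoff:
        return clock_min + MINUTES_PER_DAY
    return clock_min


def extended_to_clock(extended_min: float) -> float:
    """Reduce an extended-axis time back to a clock time in [0, 1440)."""
    return extended_min % MINUTES_PER_DAY


@dataclass
class NightAnchor:
    """Landmarks of one night, all on the extended clock of its calendar day.

    ``bedtime_min``/``getup_min`` come from the parent diary (with fallback
    to the first/last reported-sleep minute, flagged via ``*_reported``);
    ``onset_min``/``offset_min`` are derived from scored states.
    """

    night_id: int
    bedtime_min: float
    getup_min: float
    bedtime_reported: bool = True
    getup_reported: bool = True
    onset_min: float | None = None
    offset_min: float | None = None

    def __post_init__(self) -> None:
        if self.bedtime_min >= self.getup_min:
            raise ValueError(
                f"night {self.night_id}: bedtime ({self.bedtime_min}) must "
                f"precede get-up ({self.getup_min}) on the extended clock")

    @property
    def midsleep_min(self) -> float | None:
        """Midpoint of onset and offset, reduced to clock time."""
        if self.onset_min is None or self.offset_min is None:
            return None
        return extended_to_clock((self.onset_min + self.offset_min) / 2.0)

    @property
    def midsleep_extended(self) -> float | None:
        if self.onset_min is None or self.offset_min is None:
            return None
        return (self.onset_min + self.offset_min) / 2.0


@dataclass(frozen=True)
class VariableDef:
    """One entry of the 48-slot sleep-variable registry."""

    id: int
    name: str
    units: str
    family: Family
    window: Window
    is_variability: bool = False
    base_id: int | None = None  # for cross-day variability slots


def _defs() -> list[VariableDef]:
    F, W = Family, Window
    v: list[VariableDef] = []

    def base(i, name, units, family, window):
        v.append(VariableDef(i, name, units, family, window))

    def var(i, name, base_id, family):
        v.append(VariableDef(i, name, "SD", family, v[-1].window,
                             is_variability=True, base_id=base_id))

    base(1, "Bedtime", "clock min", F.CLOCK_TIME, W.NIGHT)
    var(2, "Variability of Bedtime", 1, F.CLOCK_TIME)
    base(3, "Get up Time", "clock min", F.CLOCK_TIME, W.NIGHT)
    var(4, "Variability of Get up Time", 3, F.CLOCK_TIME)
    base(5, "Sleep Onset", "clock min", F.CLOCK_TIME, W.NIGHT)
    var(6, "Variability of Sleep Onset", 5, F.CLOCK_TIME)
    base(7, "Sleep Latency", "min", F.PARTIAL_DAY, W.NIGHT)
    var(8, "Variability of Sleep Latency", 7, F.PARTIAL_DAY)
    base(9, "Sleep Offset", "clock min", F.CLOCK_TIME, W.NIGHT)
    var(10, "Variability of Sleep Offset", 9, F.CLOCK_TIME)
    base(11, "Midsleep", "clock min", F.CLOCK_TIME, W.NIGHT)
    var(12, "Variability of Midsleep", 11, F.CLOCK_TIME)
    base(13, "Sleep Opportunity", "min", F.PARTIAL_DAY, W.NIGHT)
    var(14, "Variability of Sleep Opportunity", 13, F.PARTIAL_DAY)
    base(15, "Sleep Period", "min", F.PARTIAL_DAY, W.NIGHT)
    var(16, "Variability of Sleep Period", 15, F.PARTIAL_DAY)
    base(17, "Total Sleep Time", "min", F.PARTIAL_DAY, W.NIGHT)
    var(18, "Variability of Total Sleep Time", 17, F.PARTIAL_DAY)
    base(19, "Sleep Efficiency", "%", F.ENTIRE_DAY, W.NIGHT)
    var(20, "Variability of Sleep Efficiency", 19, F.ENTIRE_DAY)
    base(21, "Wake after Sleep Onset", "min", F.PARTIAL_DAY, W.NIGHT)
    var(22, "Variability of Wake after Sleep Onset", 21, F.PARTIAL_DAY)
    base(23, "Longest Nocturnal Wake", "min", F.PARTIAL_DAY, W.NIGHT)
    var(24, "Variability of Longest Nocturnal Wake", 23, F.PARTIAL_DAY)
    base(25, "Nocturnal Wake Frequency per Hour", "wakings/hour",
         F.PARTIAL_DAY, W.NIGHT)
    var(26, "Variability of Nocturnal Wake Frequency per Hour", 25,
        F.PARTIAL_DAY)
    base(27, "Variability of Activity level", "counts (SD within night)",
         F.MOVEMENT_COUNT, W.NIGHT)
    base(28, "Percent Active Epochs", "ratio", F.MOVEMENT_COUNT, W.NIGHT)
    var(29, "Variability Percent Active Epochs", 28, F.MOVEMENT_COUNT)
    base(30, "Longest Sleep", "min", F.ENTIRE_DAY, W.FULL_24H)
    var(31, "Variability of Longest Sleep", 30, F.ENTIRE_DAY)
    base(32, "Longest Wake", "min", F.ENTIRE_DAY, W.DAY)
    var(33, "Variability of Longest Wake", 32, F.ENTIRE_DAY)
    base(34, "Nap Counter", "count", F.ENTIRE_DAY, W.DAY)
    var(35, "Variability Nap counter", 34, F.ENTIRE_DAY)
    base(36, "Sleep after Wake Onset", "min", F.ENTIRE_DAY, W.DAY)
    var(37, "Variability Sleep after Wake Onset", 36, F.ENTIRE_DAY)
    base(38, "Sleep Duration 24 h", "min", F.ENTIRE_DAY, W.FULL_24H)
    var(39, "Variability of Sleep Duration 24 h", 38, F.ENTIRE_DAY)
    base(40, "Sleep Duration Day", "min", F.ENTIRE_DAY, W.CLOCK_DAY)
    var(41, "Variability Sleep Duration Day", 40, F.ENTIRE_DAY)
    base(42, "Sleep Duration Night", "min", F.ENTIRE_DAY, W.CLOCK_NIGHT)
    var(43, "Variability of Sleep Duration Night", 42, F.ENTIRE_DAY)
    base(44, "% Sleep Duration Night", "ratio", F.ENTIRE_DAY, W.FULL_24H)
    var(45, "Variability % Sleep Duration Night", 44, F.ENTIRE_DAY)
    base(46, "Sleep Regularity Index Whole Day", "ratio", F.ENTIRE_DAY,
         W.FULL_24H)
    base(47, "Sleep Regularity Index Day", "ratio", F.ENTIRE_DAY, W.CLOCK_DAY)
    base(48, "Sleep Regularity Index Night", "ratio", F.ENTIRE_DAY,
         W.CLOCK_NIGHT)
    return v


@dataclass(frozen=True)
class VariableRegistry:
    """Immutable registry of the 48 sleep variables.

    Variability slots are cross-day standard deviations of a base variable
    (22 of the 48); variable 27, despite its historical name, is a
    within-night SD of activity and therefore a base variable.
    """

    entries: tuple[VariableDef, ...] = field(default_factory=lambda: tuple(_defs()))

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if ids != list(range(1, 49)):
            raise ValueError("registry must contain exactly ids 1..48 in order")
        by_id = {e.id: e for e in self.entries}
        for e in self.entries:
            if e.is_variability and e.base_id not in by_id:
                raise ValueError(f"variability entry {e.id} has no base")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, var_id: int) -> VariableDef:
        return self.entries[var_id - 1]

    def __iter__(self):
        return iter(self.entries)

    @property
    def base_ids(self) -> list[int]:
        return [e.id for e in self.entries if not e.is_variability]

    @property
    def variability_ids(self) -> list[int]:
        return [e.id for e in self.entries if e.is_variability]

    def column(self, var_id: int) -> str:
        """Stable machine name for tabular output, e.g. ``v19_sleep_efficiency``."""
        e = self[var_id]
        slug = (e.name.lower().replace("%", "pct").replace(" ", "_")
                .replace("/", "_"))
        return f"v{e.id:02d}_{slug}"


def registry_build() -> VariableRegistry:
    """Construct the canonical 48-variable registry."""
    return VariableRegistry()
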