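"""Minute-by-minute sleep/wake scoring.

The scorer is a Sadeh-style windowed linear classifier: for each minute a
score is formed from activity-count features in a symmetric window (mean
level, number of epochs above a level, variability, log of the current
count) and the minute is scored SLEEP when the score is >= 0.  Published
infant coefficient sets can be supplied through :class:`ScorerConfig`; the
package defaults are documented in the methods note and are deliberately
conservative (all activity features enter with non-negative weight, so
adding activity can only push a minute toward WAKE).

After the linear pass a refinement partitions minutes into high/low
activity at ``mean(activity) * 0.72`` and forces high-activity minutes to
WAKE, followed by an ordered list of run-length smoothing rules (fill short
wake islands inside sleep, delete short sleep islands inside wake) that
align the scored series with diary-scale sleep bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DIARY_SLEEP, DIARY_WAKE, MISSING, SLEEP, WAKE


@dataclass(frozen=True)
class SmoothingRule:
    """One run-length operation.

    kind='fill_wake'  : WAKE runs shorter than ``length`` flanked by SLEEP
                        on both sides become SLEEP.
    kind='drop_sleep' : SLEEP runs shorter than ``length`` flanked by WAKE
                        become WAKE.
    """

    kind: str
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("fill_wake", "drop_sleep"):
            raise ValueError(f"unknown smoothing rule kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("rule length must be >= 1")


@dataclass(frozen=True)
class ScorerConfig:
    """Coefficients and rules of the scoring engine.

    ``score = intercept - w_mean*MEAN - w_nat*NAT - w_sd*SD - w_log*ln(1+c)``
    where MEAN/SD are over counts in a ±``window_radius`` window, NAT is
    the number of window epochs with counts >= ``nat_level`` and c is the
    minute's own count.  SLEEP when score >= 0 (ties sleep).
    """

    intercept: float = 10.0
    w_mean: float = 0.03
    w_nat: float = 0.4
    w_sd: float = 0.005
    w_log: float = 0.3
    nat_level: float = 100.0
    window_radius: int = 5
    refine_threshold_factor: float = 0.72
    smoothing_rules: tuple[SmoothingRule, ...] = field(
        default_factory=lambda: (
            SmoothingRule("fill_wake", 5),
            SmoothingRule("drop_sleep", 5),
        ))

    def __post_init__(self) -> None:
        if not 0 < self.refine_threshold_factor <= 1:
            raise ValueError("refine_threshold_factor must be in (0, 1]")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


def _window_stats(counts: np.ndarray, radius: int, nat_level: float):
    """Truncated-window mean, SD and above-level count via convolution.

    NaN minutes contribute nothing to numerator or denominator.
    """
    kernel = np.ones(2 * radius + 1)
    finite = np.isfinite(counts)
    x = np.where(finite, counts, 0.0)
    n = np.convolve(finite.astype(float), kernel, mode="same")
    s1 = np.convolve(x, kernel, mode="same")
    s2 = np.convolve(x * x, kernel, mode="same")
    nat = np.convolve(np.where(finite & (counts >= nat_level), 1.0, 0.0),
                      kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = np.maximum(s2 / n - mean ** 2, 0.0)
    sd = np.sqrt(var)
    mean[n == 0] = np.nan
    sd[n == 0] = np.nan
    return mean, sd, nat


def score_probability(counts: np.ndarray, cfg: ScorerConfig = ScorerConfig()
                      ) -> np.ndarray:
    """Linear sleep score per minute; NaN where the minute is uninformed."""
    counts = np.asarray(counts, dtype=float)
    mean, sd, nat = _window_stats(counts, cfg.window_radius, cfg.nat_level)
    score = (cfg.intercept - cfg.w_mean * mean - cfg.w_nat * nat
             - cfg.w_sd * sd - cfg.w_log * np.log1p(np.maximum(counts, 0.0)))
    score[~np.isfinite(counts)] = np.nan
    return score


def classify(counts: np.ndarray, cfg: ScorerConfig = ScorerConfig()
             ) -> np.ndarray:
    """SLEEP/WAKE/MISSING states from the linear score (ties -> SLEEP)."""
    score = score_probability(counts, cfg)
    states = np.full(score.shape, MISSING, dtype=np.int8)
    states[score >= 0] = SLEEP
    states[score < 0] = WAKE
    return states


def refine_high_low(counts: np.ndarray, states: np.ndarray,
                    factor: float = 0.72) -> np.ndarray:
    """Force high-activity minutes to WAKE.

    The high/low partition uses threshold = mean(activity) * factor, the
    mean taken over informed (finite-count, non-MISSING) minutes.  Raises
    on an all-missing recording.
    """
    counts = np.asarray(counts, dtype=float)
    states = np.asarray(states, dtype=np.int8).copy()
    informed = np.isfinite(counts) & (states != MISSING)
    if not informed.any():
        raise ValueError("cannot refine: no informed minutes in recording")
    threshold = np.nanmean(counts[informed]) * factor
    high = informed & (counts >= threshold)
    states[high & (states == SLEEP)] = WAKE
    return states


def high_low_threshold(counts: np.ndarray, factor: float = 0.72) -> float:
    """The high/low activity threshold: mean over finite counts × factor."""
    counts = np.asarray(counts, dtype=float)
    finite = counts[np.isfinite(counts)]
    if finite.size == 0:
        raise ValueError("no finite counts")
    return float(finite.mean() * factor)


def _runs(states: np.ndarray):
    """(value, start, length) tuples of maximal runs."""
    n = states.size
    if n == 0:
        return []
    edges = np.flatnonzero(np.diff(states)) + 1
    starts = np.r_[0, edges]
    ends = np.r_[edges, n]
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _apply_rule(states: np.ndarray, rule: SmoothingRule) -> np.ndarray:
    target, repl = ((WAKE, SLEEP) if rule.kind == "fill_wake"
                    else (SLEEP, WAKE))
    out = states.copy()
    runs = _runs(states)
    for i, (val, start, length) in enumerate(runs):
        if val != target or length >= rule.length:
            continue
        left = runs[i - 1][0] if i > 0 else None
        right = runs[i + 1][0] if i + 1 < len(runs) else None
        if left == repl and right == repl:
            out[start:start + length] = repl
    return out


def apply_smoothing(states: np.ndarray,
                    rules: tuple[SmoothingRule, ...]) -> np.ndarray:
    """Apply run-length rules in order, iterating to a fixed point.

    MISSING minutes are never altered and act as run boundaries (an island
    adjacent to MISSING is not flanked and is left alone).  The fixed-point
    iteration makes the whole operation idempotent by construction.
    """
    states = np.asarray(states, dtype=np.int8)
    current = states.copy()
    for _ in range(10):
        nxt = current
        for rule in rules:
            nxt = _apply_rule(nxt, rule)
        if np.array_equal(nxt, current):
            break
        current = nxt
    current[states == MISSING] = MISSING
    return current


def score_recording(minutes: pd.DataFrame,
                    cfg: ScorerConfig = ScorerConfig()) -> pd.DataFrame:
    """Full scoring pass over a minute grid from :func:`ingest.fuse_diary`.

    Worn, sensor-informed minutes are scored by the linear classifier,
    refined at the high/low threshold and smoothed; non-wear (or
    count-less) minutes take the diary state where reported and are
    MISSING otherwise.  Returns a copy with a ``state`` column.
    """
    out = minutes.copy()
    counts = out["activity"].to_numpy(dtype=float)
    worn = out["wear"].to_numpy(dtype=bool) & np.isfinite(counts)

    masked = np.where(worn, counts, np.nan)
    states = classify(masked, cfg)
    if worn.any():
        states = refine_high_low(masked, states, cfg.refine_threshold_factor)
        states = apply_smoothing(states, cfg.smoothing_rules)

    diary = out["diary_state"].to_numpy(dtype=np.int8)
    fallback = ~worn
    states[fallback & (diary == DIARY_SLEEP)] = SLEEP
    states[fallback & (diary == DIARY_WAKE)] = WAKE
    out["state"] = states
    return out
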