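"""Free-running period, phase shifts, jet-lag re-entrainment and FAA.

Sign convention throughout: phase advances are positive, delays negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .telemetry import (
    HOURS_PER_DAY,
    FeedingSchedule,
    LightSchedule,
    TelemetrySeries,
)
from .episodes import DailyEpisode, onset_error_dd

__all__ = [
    "RegressionFit",
    "PhaseShiftResult",
    "ReentrainmentResult",
    "FAAResult",
    "fit_tau",
    "phase_shift_type2",
    "reentrainment_days",
    "activity_midpoint",
    "faa",
]


@dataclass
class RegressionFit:
    """Least-squares line through successive onsets: slope is tau (h/cycle)."""

    tau: float
    intercept: float
    n_onsets: int
    rms_error: float
    accepted: bool = True      # False when tau falls outside (20, 28) h

    def predict(self, cycle) -> np.ndarray:
        return self.intercept + self.tau * np.asarray(cycle, dtype=float)


@dataclass
class PhaseShiftResult:
    shift: float               # hours; advance positive, delay negative
    pulse_pzt: float
    n_post_onsets: int
    transients_omitted: int = 3


@dataclass
class ReentrainmentResult:
    days_to_criterion: int | None    # None = not re-entrained in the record
    criterion_shift: float
    tolerance: float
    basis: str                       # "onset" or "midpoint"
    daily_shifts: np.ndarray
    days_observed: int

    @property
    def criterion_fraction(self) -> float:
        """Fraction of the imposed shift that must be completed; the 6 +/- 0.3 h
        convention corresponds to 95% of a 6-h shift."""
        return (self.criterion_shift - self.tolerance) / self.criterion_shift

    @property
    def reentrained(self) -> bool:
        return self.days_to_criterion is not None


@dataclass
class FAAResult:
    faa_fraction: dict[int, float]    # day -> proportion in [0, 1] (NaN ok)
    day_type: dict[int, str]
    window_hours: float = 3.0
    reference_food_time_zt: float = 8.0

    def on_days(self, kind: str) -> list[float]:
        return [self.faa_fraction[d] for d in sorted(self.faa_fraction)
                if self.day_type[d] == kind]


def fit_tau(episodes: list[DailyEpisode]) -> RegressionFit:
    """Free-running period as the OLS slope of onset time (absolute hours)
    against cycle index."""
    det = [e for e in episodes if e.detected]
    if len(det) < 3:
        raise ValueError("need >= 3 detected onsets")
    cycles = np.array([e.cycle_index for e in det], dtype=float)
    onsets = np.array([e.onset for e in det])
    slope, intercept = np.polyfit(cycles, onsets, 1)
    fit = RegressionFit(tau=float(slope), intercept=float(intercept),
                        n_onsets=len(det), rms_error=0.0,
                        accepted=20.0 < slope < 28.0)
    fit.rms_error = onset_error_dd(episodes, fit)
    return fit


def phase_shift_type2(
    pre_episodes: list[DailyEpisode],
    post_episodes: list[DailyEpisode],
    pulse_time: float,
    transients_omitted: int = 3,
    max_post_onsets: int = 7,
    pulse_pzt: float = np.nan,
) -> PhaseShiftResult:
    """Aschoff Type II phase shift.

    The pre-pulse free run is regressed and extrapolated to the cycle of
    the light pulse (this also supplies the pulse-day onset when the pulse
    itself disturbs that night's activity); the post-pulse rhythm is
    regressed on 6-7 onsets after omitting the transient cycles, and
    extrapolated back to the pulse cycle. Shift = pre-line minus post-line
    at the pulse cycle, so an advance (earlier onsets) is positive.

    Cycle indices must be on one global numbering across pre and post.
    """
    pre_fit = fit_tau(pre_episodes)
    post_det = [e for e in post_episodes if e.detected]
    post_used = post_det[transients_omitted:
                         transients_omitted + max_post_onsets]
    if len(post_used) < 6:
        raise ValueError(
            "need >= 6 post-pulse onsets after omitting transients")
    post_fit = fit_tau(post_used)
    # cycle containing the pulse: last pre-line onset at or before the pulse
    c_pulse = int(np.floor((pulse_time - pre_fit.intercept) / pre_fit.tau))
    pre_at_pulse = pre_fit.predict(c_pulse)
    post_at_pulse = post_fit.predict(c_pulse)
    return PhaseShiftResult(
        shift=float(pre_at_pulse - post_at_pulse),
        pulse_pzt=pulse_pzt,
        n_post_onsets=len(post_used),
        transients_omitted=transients_omitted,
    )


def reentrainment_days(
    episodes: list[DailyEpisode],
    shift_imposed: float = 6.0,
    tolerance: float = 0.3,
    basis: str = "onset",
    shift_time: float | None = None,
    midpoints: np.ndarray | None = None,
    stability_guard: bool = True,
) -> ReentrainmentResult:
    """Days to re-entrain after an abrupt photocycle advance.

    The reference phase is the mean pre-shift onset (or midpoint) clock
    time; each post-shift day's achieved shift is the advance of that day's
    phase marker relative to the reference. Criterion: the first post-shift
    day whose achieved shift is >= shift_imposed - tolerance, by default
    also requiring the next day to satisfy it (stability guard against
    sporadic advanced onsets).
    """
    if shift_time is None:
        raise ValueError("shift_time (hours, schedule shift) is required")
    if basis not in ("onset", "midpoint"):
        raise ValueError("basis must be 'onset' or 'midpoint'")
    det = [e for e in episodes if e.detected]
    if basis == "onset":
        times = {e.cycle_index: e.onset for e in det}
    else:
        if midpoints is None:
            raise ValueError("midpoint basis needs the midpoints array")
        times = {e.cycle_index: m for e, m in zip(episodes, midpoints)
                 if e.detected and np.isfinite(m)}
    pre = {c: t for c, t in times.items()
           if t < shift_time}
    post = {c: t for c, t in times.items() if t >= shift_time}
    if len(pre) < 3:
        raise ValueError("need >= 3 pre-shift cycles for the baseline")
    base_clock = np.mean([t - HOURS_PER_DAY * c for c, t in pre.items()])
    # post-shift day numbers come from the cycle index so undetected cycles
    # leave a gap instead of renumbering the days that follow
    c0 = max(pre) + 1
    post_cycles = sorted(post)
    if not post_cycles:
        return ReentrainmentResult(None, shift_imposed, tolerance, basis,
                                   np.array([]), 0)
    n_days = post_cycles[-1] - c0 + 1
    shifts = np.full(n_days, np.nan)
    for c in post_cycles:
        shifts[c - c0] = base_clock - (post[c] - HOURS_PER_DAY * c)
    met = shifts >= (shift_imposed - tolerance)   # NaN compares False
    days = None
    for i in range(n_days):
        if not met[i]:
            continue
        if stability_guard:
            if i + 1 < n_days and met[i + 1]:
                days = i + 1
                break
        else:
            days = i + 1
            break
    return ReentrainmentResult(
        days_to_criterion=days,
        criterion_shift=shift_imposed,
        tolerance=tolerance,
        basis=basis,
        daily_shifts=shifts,
        days_observed=n_days,
    )


def activity_midpoint(
    series: TelemetrySeries, episodes: list[DailyEpisode]
) -> np.ndarray:
    """Per-cycle midpoint of activity: center of mass of counts within
    onset -> offset, in hours from series start (NaN for undetected)."""
    t = series.bin_centers_h
    out = np.full(len(episodes), np.nan)
    for i, e in enumerate(episodes):
        if not e.detected:
            continue
        sel = (t >= e.onset) & (t < e.offset)
        w = series.lma[sel]
        if w.sum() > 0:
            out[i] = float(np.average(t[sel], weights=w))
    return out


def faa(
    series: TelemetrySeries,
    feeding: FeedingSchedule,
    schedule: LightSchedule,
    window: float = 3.0,
) -> FAAResult:
    """Food-anticipatory activity: per scheduled day, the proportion of that
    day's counts falling in the ``window`` hours immediately before the
    actual (training) or expected (ad-lib / retention) mealtime."""
    t = series.bin_centers_h
    fractions: dict[int, float] = {}
    kinds: dict[int, str] = {}
    for day in feeding.days:
        zt0 = schedule.zt0_of_day(day)
        day_sel = (t >= zt0) & (t < zt0 + HOURS_PER_DAY)
        food_t = zt0 + feeding.food_time_zt(day)
        win_sel = (t >= food_t - window) & (t < food_t)
        total = series.lma[day_sel].sum()
        kinds[day] = feeding.day_type(day)
        fractions[day] = (float(series.lma[win_sel].sum() / total)
                          if total > 0 else np.nan)
    return FAAResult(
        faa_fraction=fractions, day_type=kinds, window_hours=window,
        reference_food_time_zt=feeding.expected_food_time_zt,
    )
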