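"""Telemetry data model, file I/O and experimental time conventions.

Telemetry records are uniformly sampled locomotor-activity (LMA) counts and
core body temperature (T_b) at a nominal 1-min resolution, as produced by
implanted-transmitter logging systems. Lighting and feeding protocols are
represented as explicit schedules from which Zeitgeber time (ZT; ZT0 =
lights-on, ZT12 = lights-off) and projected ZT (pZT, extrapolated into
constant darkness at 24.0 h/cycle from the last lights-off) are derived.

Internally all times are hours from the schedule/series origin; the CSV
dialect carries ISO-8601 timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TelemetrySeries",
    "LightSegment",
    "LightPulse",
    "LightSchedule",
    "FeedingSchedule",
    "ZTTime",
    "read_telemetry",
    "write_telemetry",
    "rebin",
    "zt_of",
    "quality_mask",
    "light_schedule_from_dict",
    "feeding_schedule_from_dict",
]

MINUTES_PER_HOUR = 60.0
HOURS_PER_DAY = 24.0


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class TelemetrySeries:
    """Uniformly sampled activity + body-temperature record for one subject.

    Parameters
    ----------
    start_time
        Calendar timestamp of the first bin's left edge.
    bin_width
        Bin width in minutes.
    lma
        Non-negative activity counts per bin.
    tb
        Core body temperature (deg C) per bin; NaN where missing.
    missing_mask
        True where T_b is missing/unusable. Masked bins are excluded from
        every downstream mean; LMA counts in masked bins are retained.
    """

    start_time: pd.Timestamp
    bin_width: float
    lma: np.ndarray
    tb: np.ndarray
    missing_mask: np.ndarray
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.lma = np.asarray(self.lma, dtype=float)
        self.tb = np.asarray(self.tb, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.lma) == len(self.tb) == len(self.missing_mask)):
            raise ValueError("lma, tb and missing_mask must have equal length")
        if np.any(self.lma < 0):
            raise ValueError("activity counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def __len__(self) -> int:
        return len(self.lma)

    @property
    def n_bins(self) -> int:
        return len(self.lma)

    @property
    def duration_h(self) -> float:
        """Covered duration in hours (bin count x bin width, exactly)."""
        return self.n_bins * self.bin_width / MINUTES_PER_HOUR

    @property
    def times_h(self) -> np.ndarray:
        """Left bin edges in hours from ``start_time``."""
        return np.arange(self.n_bins) * (self.bin_width / MINUTES_PER_HOUR)

    @property
    def bin_centers_h(self) -> np.ndarray:
        return self.times_h + 0.5 * self.bin_width / MINUTES_PER_HOUR

    def tb_masked(self) -> np.ndarray:
        """T_b with masked bins as NaN."""
        out = self.tb.copy()
        out[self.missing_mask] = np.nan
        return out


@dataclass(frozen=True)
class LightSegment:
    """One homogeneous stretch of the lighting protocol.

    kind is "LD", "DD" or "LL"; for LD, ``lights_on``/``lights_off`` are
    clock hours of day in [0, 24).
    """

    kind: str
    days: float
    lights_on: float = 6.0
    lights_off: float = 18.0

    def __post_init__(self) -> None:
        if self.kind not in ("LD", "DD", "LL"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.days <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class LightPulse:
    start_h: float        # hours from schedule origin
    duration_min: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass
class LightSchedule:
    """Ordered lighting segments tiling the experiment without gaps.

    ``start_clock`` is the clock hour of day at schedule time 0 (hours).
    ``reference_lights_off_h`` anchors pZT for schedules that begin in
    DD/LL; for schedules containing an LD segment it defaults to the last
    lights-off event of the final LD segment.
    """

    segments: list[LightSegment]
    pulses: list[LightPulse] = field(default_factory=list)
    start_clock: float = 6.0
    reference_lights_off_h: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")

    # -- geometry ----------------------------------------------------------
    @property
    def span_h(self) -> float:
        return sum(s.days for s in self.segments) * HOURS_PER_DAY

    def segment_bounds(self) -> list[tuple[float, float, LightSegment]]:
        out, t = [], 0.0
        for s in self.segments:
            out.append((t, t + s.days * HOURS_PER_DAY, s))
            t += s.days * HOURS_PER_DAY
        return out

    def segment_at(self, t: float) -> tuple[float, float, LightSegment]:
        if t < 0:
            raise ValueError("time before schedule start")
        for lo, hi, s in self.segment_bounds():
            if lo <= t < hi:
                return lo, hi, s
        lo, hi, s = self.segment_bounds()[-1]
        if np.isclose(t, hi):
            return lo, hi, s
        raise ValueError(f"time {t} h beyond schedule span {self.span_h} h")

    def clock_of(self, t: float) -> float:
        return (self.start_clock + t) % HOURS_PER_DAY

    # -- photic events -----------------------------------------------------
    def _events(self, clock_hour_attr: str) -> np.ndarray:
        """Absolute hours of lights-on or lights-off events in LD segments."""
        events = []
        for lo, hi, seg in self.segment_bounds():
            if seg.kind != "LD":
                continue
            target = getattr(seg, clock_hour_attr)
            first = lo + (target - self.clock_of(lo)) % HOURS_PER_DAY
            t = first
            while t < hi - 1e-9:
                events.append(t)
                t += HOURS_PER_DAY
        return np.array(events)

    def lights_off_events(self) -> np.ndarray:
        return self._events("lights_off")

    def lights_on_events(self) -> np.ndarray:
        return self._events("lights_on")

    def last_lights_off_before(self, t: float) -> float:
        ev = self.lights_off_events()
        ev = ev[ev <= t + 1e-9]
        if ev.size:
            return float(ev[-1])
        if self.reference_lights_off_h is not None:
            return self.reference_lights_off_h
        raise ValueError(
            "no lights-off event before t and no reference_lights_off_h set"
        )

    def zt0_of_day(self, day: int) -> float:
        """Absolute hour of ZT0 (lights-on / projected lights-on) of day."""
        # ZT0 of day d sits 12 h before the day's (projected) lights-off.
        ev = self.lights_off_events()
        lo, hi = day * HOURS_PER_DAY, (day + 1) * HOURS_PER_DAY
        on_day = ev[(ev >= lo) & (ev < hi)] if ev.size else np.array([])
        ref = float(on_day[0]) if on_day.size else self.reference_lights_off()
        phase = ref % HOURS_PER_DAY
        return day * HOURS_PER_DAY + (phase - 12.0) % HOURS_PER_DAY

    def reference_lights_off(self) -> float:
        ev = self.lights_off_events()
        if ev.size:
            return float(ev[-1])
        if self.reference_lights_off_h is None:
            raise ValueError("schedule has no LD segment and no reference")
        return self.reference_lights_off_h


@dataclass
class FeedingSchedule:
    """Day-indexed food-availability windows in ZT hours.

    ``windows`` maps ZT-day index -> (zt_start, zt_end) of food access;
    days in ``adlib_days`` have unrestricted food; ``deprivation_days``
    have none. ``expected_food_time_zt`` is the trained mealtime used on
    retention-trial (deprivation) days.
    """

    windows: dict[int, tuple[float, float]] = field(default_factory=dict)
    adlib_days: set[int] = field(default_factory=set)
    deprivation_days: set[int] = field(default_factory=set)
    expected_food_time_zt: float = 8.0

    def __post_init__(self) -> None:
        for d, (a, b) in self.windows.items():
            if not (0 <= a < HOURS_PER_DAY):
                raise ValueError(f"window start {a} outside [0, 24) on day {d}")
            if d in self.deprivation_days:
                raise ValueError(f"deprivation day {d} cannot have a window")

    @property
    def days(self) -> list[int]:
        return sorted(set(self.windows) | self.adlib_days | self.deprivation_days)

    @property
    def training_days(self) -> list[int]:
        return sorted(self.windows)

    def day_type(self, day: int) -> str:
        if day in self.deprivation_days:
            return "retention"
        if day in self.adlib_days:
            return "adlib"
        if day in self.windows:
            return "training"
        raise KeyError(f"day {day} not in feeding schedule")

    def food_time_zt(self, day: int) -> float:
        """Actual (training) or expected (ad-lib / retention) mealtime, ZT h."""
        if day in self.windows:
            return self.windows[day][0]
        return self.expected_food_time_zt

    @classmethod
    def rf_protocol(
        cls,
        n_training_days: int = 12,
        start_day: int = 0,
        n_adlib_days: int = 2,
        n_deprivation_days: int = 2,
    ) -> "FeedingSchedule":
        """Restricted-feeding ramp: day 1 ZT8-16, day 2 ZT8-14, then ZT8-12,
        followed by ad-lib days and a 48-h deprivation retention trial."""
        windows: dict[int, tuple[float, float]] = {}
        for i in range(n_training_days):
            d = start_day + i
            if i == 0:
                windows[d] = (8.0, 16.0)
            elif i == 1:
                windows[d] = (8.0, 14.0)
            else:
                windows[d] = (8.0, 12.0)
        adlib = {start_day + n_training_days + i for i in range(n_adlib_days)}
        depriv = {
            start_day + n_training_days + n_adlib_days + i
            for i in range(n_deprivation_days)
        }
        return cls(windows=windows, adlib_days=adlib, deprivation_days=depriv)


@dataclass(frozen=True)
class ZTTime:
    """Zeitgeber time in hours; ``projected`` marks pZT extrapolated in DD."""

    value: float
    projected: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.value < HOURS_PER_DAY):
            raise ValueError("ZT must lie in [0, 24)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_telemetry(path, subject_id: str = "", group_label: str = "") -> TelemetrySeries:
    """Read the telemetry CSV dialect: header ``timestamp,lma,tb``, ISO-8601
    timestamps at a constant nominal interval, literal ``NA`` for missing T_b.

    Unparseable T_b rows are masked, never dropped. Non-monotone or
    duplicated timestamps are hard errors.
    """
    df = pd.read_csv(path, dtype={"timestamp": str, "lma": float, "tb": str})
    required = {"timestamp", "lma", "tb"}
    if not required.issubset(df.columns):
        raise ValueError(f"telemetry CSV must have columns {sorted(required)}")
    ts = pd.to_datetime(df["timestamp"])
    if ts.duplicated().any():
        first = ts[ts.duplicated()].iloc[0]
        raise ValueError(f"duplicate timestamp: {first}")
    diffs = ts.diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        raise ValueError("timestamps must be strictly increasing")
    if len(ts) > 1:
        if diffs.nunique() != 1:
            raise ValueError("timestamps must be on a constant interval")
        bin_width = diffs.iloc[0].total_seconds() / 60.0
    else:
        bin_width = 1.0
    def _parse_tb(x) -> float:
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    tb = np.array([_parse_tb(x) for x in df["tb"]])
    mask = ~np.isfinite(tb)
    return TelemetrySeries(
        start_time=ts.iloc[0],
        bin_width=bin_width,
        lma=df["lma"].to_numpy(),
        tb=tb,
        missing_mask=mask,
        subject_id=subject_id,
        group_label=group_label,
    )


def write_telemetry(series: TelemetrySeries, path) -> None:
    """Write a series in the CSV dialect read by :func:`read_telemetry`."""
    ts = series.start_time + pd.to_timedelta(
        np.arange(series.n_bins) * series.bin_width, unit="m"
    )
    tb_col = [
        "NA" if m else repr(float(v))
        for v, m in zip(series.tb, series.missing_mask)
    ]
    df = pd.DataFrame({
        "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
        "lma": series.lma.astype(int),
        "tb": tb_col,
    })
    df.to_csv(path, index=False)


def rebin(series: TelemetrySeries, width: float) -> TelemetrySeries:
    """Re-bin to a coarser grid: LMA summed, T_b averaged over unmasked bins.

    ``width`` (minutes) must be a positive multiple of the series bin width
    and divide 24 h. A window whose bins are all masked stays masked.
    """
    ratio = width / series.bin_width
    if width <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("width must be a positive multiple of bin_width")
    if abs((HOURS_PER_DAY * MINUTES_PER_HOUR) % width) > 1e-9:
        raise ValueError("width must divide 24 h")
    k = int(round(ratio))
    if k == 1:
        return replace(series)
    n = (series.n_bins // k) * k
    lma = series.lma[:n].reshape(-1, k).sum(axis=1)
    tbm = series.tb_masked()[:n].reshape(-1, k)
    good = np.isfinite(tbm)
    n_good = good.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tb = np.where(n_good > 0, np.nansum(np.where(good, tbm, 0.0), axis=1)
                      / np.maximum(n_good, 1), np.nan)
    mask = n_good == 0
    return TelemetrySeries(
        start_time=series.start_time,
        bin_width=width,
        lma=lma,
        tb=tb,
        missing_mask=mask,
        subject_id=series.subject_id,
        group_label=series.group_label,
    )


def zt_of(t: float, schedule: LightSchedule) -> ZTTime:
    """Zeitgeber time of absolute hour ``t``.

    Under LD, lights-on maps to ZT0 and lights-off to ZT12. Under DD/LL the
    return value is projected ZT, extrapolated at exactly 24.0 h/cycle from
    the last lights-off.
    """
    if t < 0:
        raise ValueError("time before schedule start")
    _, _, seg = schedule.segment_at(t)
    if seg.kind == "LD":
        return ZTTime(value=(schedule.clock_of(t) - seg.lights_on) % HOURS_PER_DAY,
                      projected=False)
    ref = schedule.last_lights_off_before(t)
    return ZTTime(value=(12.0 + (t - ref)) % HOURS_PER_DAY, projected=True)


def quality_mask(
    series: TelemetrySeries, max_missing_frac_per_day: float = 0.05
) -> np.ndarray:
    """Per-day usability flags: a day is unusable if its masked fraction
    exceeds the threshold. Days are consecutive 24-h blocks on the grid;
    a trailing partial day is judged on its available bins."""
    per_day = int(round(HOURS_PER_DAY * MINUTES_PER_HOUR / series.bin_width))
    if series.n_bins < 1:
        raise ValueError("empty series")
    n_days = int(np.ceil(series.n_bins / per_day))
    flags = np.empty(n_days, dtype=bool)
    for d in range(n_days):
        chunk = series.missing_mask[d * per_day:(d + 1) * per_day]
        flags[d] = chunk.mean() <= max_missing_frac_per_day
    return flags


# ---------------------------------------------------------------------------
# structured-config parsing (JSON/YAML-friendly dictionaries)
# ---------------------------------------------------------------------------

def _clock_hours(v) -> float:
    """Accept 6, 6.5 or 'HH:MM' clock strings."""
    if isinstance(v, str):
        h, m = v.split(":")
        return float(h) + float(m) / 60.0
    return float(v)


def light_schedule_from_dict(cfg: dict) -> LightSchedule:
    """Build a LightSchedule from the documented config mapping, e.g.::

        {"light": [{"type": "LD", "on": "06:00", "off": "18:00", "days": 12},
                   {"type": "DD", "days": 11}],
         "pulses": [{"start_h": 339.0, "duration_min": 15, "label": "pZT15"}],
         "start_clock": "06:00"}
    """
    segs = []
    for s in cfg["light"]:
        kind = s.get("type", s.get("kind"))
        if kind == "LD":
            segs.append(LightSegment(
                "LD", days=float(s["days"]),
                lights_on=_clock_hours(s.get("on", "06:00")),
                lights_off=_clock_hours(s.get("off", "18:00")),
            ))
        else:
            segs.append(LightSegment(kind, days=float(s["days"])))
    pulses = [
        LightPulse(float(p["start_h"]), float(p.get("duration_min", 15.0)),
                   p.get("label", ""))
        for p in cfg.get("pulses", [])
    ]
    start_clock = _clock_hours(cfg.get("start_clock",
                                       cfg["light"][0].get("on", "06:00")
                                       if cfg["light"][0].get("type") == "LD"
                                       else 6.0))
    return LightSchedule(
        segments=segs, pulses=pulses, start_clock=start_clock,
        reference_lights_off_h=cfg.get("reference_lights_off_h"),
    )


def feeding_schedule_from_dict(cfg: dict) -> FeedingSchedule:
    """Build a FeedingSchedule from config. Either an explicit mapping
    (``windows``/``adlib_days``/``deprivation_days``) or the shorthand
    ``{"rf": {"start_day": 3, "training_days": 12}}`` for the standard
    restricted-feeding ramp."""
    if "rf" in cfg:
        rf = cfg["rf"]
        return FeedingSchedule.rf_protocol(
            n_training_days=int(rf.get("training_days", 12)),
            start_day=int(rf.get("start_day", 0)),
            n_adlib_days=int(rf.get("adlib_days", 2)),
            n_deprivation_days=int(rf.get("deprivation_days", 2)),
        )
    return FeedingSchedule(
        windows={int(k): tuple(map(float, v))
                 for k, v in cfg.get("windows", {}).items()},
        adlib_days={int(d) for d in cfg.get("adlib_days", [])},
        deprivation_days={int(d) for d in cfg.get("deprivation_days", [])},
        expected_food_time_zt=float(cfg.get("expected_food_time_zt", 8.0)),
    )
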