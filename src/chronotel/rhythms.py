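"""Rhythm strength and waveform statistics.

Implements the classical (Scargle-normalized) Lomb-Scargle periodogram PN
over a circadian period band, the non-parametric M10/L5 relative amplitude,
folded daily activity/T_b profiles, and light/dark (or subjective day/night)
phase summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle

from .telemetry import (
    HOURS_PER_DAY,
    LightSchedule,
    TelemetrySeries,
    zt_of,
)
from .episodes import DailyEpisode

__all__ = [
    "PeriodogramResult",
    "AmplitudeResult",
    "PhaseSummary",
    "lomb_scargle",
    "npcra_amplitude",
    "daily_profile",
    "phase_summary",
]


@dataclass
class PeriodogramResult:
    periods: np.ndarray          # trial periods, h (strictly increasing)
    pn: np.ndarray               # normalized power per period
    peak_period: float
    peak_pn: float
    significance_pn: float       # threshold power at the false-alarm prob.
    fap: float

    def significant(self) -> bool:
        return self.peak_pn > self.significance_pn


@dataclass
class AmplitudeResult:
    m_mean: float                # counts/bin over the most-active window
    l_mean: float                # counts/bin over the least-active window
    m_window_start: float        # hours into the folded day
    l_window_start: float
    relative_amplitude: float    # (M - L)/(M + L), in [0, 1]
    absolute_amplitude: float    # M - L, device units


@dataclass
class PhaseSummary:
    dark_counts: float
    light_counts: float
    dark_tb: float
    light_tb: float
    n_dark_bins: int
    n_light_bins: int
    labels: tuple[str, str] = ("scotophase", "photophase")

    @property
    def total_counts(self) -> float:
        return self.dark_counts + self.light_counts

    @property
    def mean_tb(self) -> float:
        """24-h mean T_b (bin-weighted over unmasked bins)."""
        n = self.n_dark_bins + self.n_light_bins
        if n == 0:
            return np.nan
        return (self.dark_tb * self.n_dark_bins
                + self.light_tb * self.n_light_bins) / n


def lomb_scargle(
    series: TelemetrySeries,
    period_range: tuple[float, float] = (20.0, 28.0),
    oversample: float = 4.0,
    fap: float = 0.001,
    channel: str = "lma",
) -> PeriodogramResult:
    """Classical Lomb-Scargle periodogram of the (unevenly usable) series.

    Power is Scargle-normalized: PN(p) equals the least-squares sinusoid
    fit's explained sum of squares at trial period p divided by twice the
    sample variance of the mean-subtracted data. The significance threshold
    maps the false-alarm probability through the independent-frequencies
    approximation, PN_sig = ln(M / fap), with M the number of independent
    frequencies spanned by the band.
    """
    p_lo, p_hi = period_range
    bw_h = series.bin_width / 60.0
    span = series.duration_h
    if not 0 < p_lo < p_hi:
        raise ValueError("invalid period range")
    if p_lo < 2 * bw_h or p_hi > span / 3.0:
        raise ValueError("period range must lie within (2*bin, span/3)")
    t = series.bin_centers_h
    if channel == "lma":
        y = series.lma.astype(float)
        good = np.ones(len(y), dtype=bool)   # LMA is kept in masked bins
    else:
        y = series.tb_masked()
        good = np.isfinite(y)
    good = good & np.isfinite(y)
    t, y = t[good], y[good]
    if t.size < 8:
        raise ValueError("too few usable samples")
    y = y - y.mean()
    var = y.var(ddof=1)
    # frequency grid: oversampled relative to the 1/span Fourier spacing
    f_lo, f_hi = 1.0 / p_hi, 1.0 / p_lo
    df = 1.0 / (span * oversample)
    freqs = np.arange(f_lo, f_hi + df, df)
    omega = 2.0 * np.pi * freqs
    if var <= 0:
        pn = np.zeros_like(omega)
    else:
        pn = _scipy_lombscargle(t, y, omega) / var
    periods = 1.0 / freqs[::-1]
    pn = pn[::-1]
    i = int(np.argmax(pn))
    m_indep = max(span * (f_hi - f_lo), 1.0)
    return PeriodogramResult(
        periods=periods, pn=pn,
        peak_period=float(periods[i]), peak_pn=float(pn[i]),
        significance_pn=float(np.log(m_indep / fap)), fap=fap,
    )


def fold_profile(
    series: TelemetrySeries, fold_period: float, channel: str = "lma"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fold the series at ``fold_period``: per folded-bin mean, SEM and day
    count. Returns (bin_start_h, mean, sem, n)."""
    bw_h = series.bin_width / 60.0
    n_fold = int(round(fold_period / bw_h))
    t = series.times_h
    idx = np.minimum((np.mod(t, fold_period) / fold_period * n_fold)
                     .astype(int), n_fold - 1)
    if channel == "lma":
        vals = series.lma.astype(float)
        ok = np.ones(len(vals), dtype=bool)
    else:
        vals = series.tb_masked()
        ok = np.isfinite(vals)
    mean = np.full(n_fold, np.nan)
    sem = np.full(n_fold, np.nan)
    n = np.zeros(n_fold, dtype=int)
    for b in range(n_fold):
        sel = (idx == b) & ok
        n[b] = sel.sum()
        if n[b]:
            v = vals[sel]
            mean[b] = v.mean()
            sem[b] = v.std(ddof=1) / np.sqrt(n[b]) if n[b] > 1 else 0.0
    return np.arange(n_fold) * bw_h, mean, sem, n


def npcra_amplitude(
    series: TelemetrySeries,
    m_hours: float = 10.0,
    l_hours: float = 5.0,
) -> AmplitudeResult:
    """Non-parametric circadian rhythm amplitude from the mean 24-h profile:
    M = maximum mean activity over any contiguous (circularly wrapped)
    window of ``m_hours``, L = minimum over windows of ``l_hours``,
    relative amplitude = (M - L)/(M + L)."""
    if m_hours > HOURS_PER_DAY or l_hours > HOURS_PER_DAY:
        raise ValueError("window longer than 24 h")
    if series.duration_h < HOURS_PER_DAY:
        raise ValueError("need at least one full day")
    starts, mean, _, _ = fold_profile(series, HOURS_PER_DAY, channel="lma")
    bw_h = HOURS_PER_DAY / len(mean)

    def window_means(w_hours: float) -> np.ndarray:
        k = int(round(w_hours / bw_h))
        ext = np.concatenate([mean, mean[:k - 1]])
        kernel = np.ones(k) / k
        return np.convolve(ext, kernel, mode="valid")

    m_means = window_means(m_hours)
    l_means = window_means(l_hours)
    im, il = int(np.argmax(m_means)), int(np.argmin(l_means))
    m, l = float(m_means[im]), float(l_means[il])
    denom = m + l
    ra = (m - l) / denom if denom > 0 else 0.0
    return AmplitudeResult(
        m_mean=m, l_mean=l,
        m_window_start=float(starts[im]), l_window_start=float(starts[il]),
        relative_amplitude=ra, absolute_amplitude=m - l,
    )


def daily_profile(
    series: TelemetrySeries,
    schedule: LightSchedule | None = None,
    fold_period: float = HOURS_PER_DAY,
    channel: str = "lma",
) -> dict[str, np.ndarray]:
    """Mean +/- SEM waveform folded at ``fold_period`` (24.0 h in LD, the
    fitted free-running period in DD). Masked bins are excluded per-bin."""
    if not 20.0 < fold_period < 28.0:
        raise ValueError("fold_period outside (20, 28) h")
    if series.duration_h < 2 * fold_period:
        raise ValueError("need >= 2 folded cycles")
    starts, mean, sem, n = fold_profile(series, fold_period, channel=channel)
    return {"bin_start_h": starts, "mean": mean, "sem": sem, "n": n}


def phase_summary(
    series: TelemetrySeries,
    schedule: LightSchedule,
    episodes: list[DailyEpisode] | None = None,
) -> PhaseSummary:
    """Totals and T_b means per phase.

    In LD the photocycle defines the phases (scotophase = ZT12-24). In DD
    the detected episodes supply the subjective-night boundaries
    (onset -> offset per cycle) and the labels become subjective
    night/day.
    """
    t = series.bin_centers_h
    has_ld = schedule.lights_off_events().size > 0
    if has_ld:
        zt = np.array([zt_of(x, schedule).value for x in t])
        dark = zt >= 12.0
        labels = ("scotophase", "photophase")
    else:
        if not episodes:
            raise ValueError("DD phase summary needs detected episodes")
        dark = np.zeros(len(t), dtype=bool)
        for e in episodes:
            if e.detected:
                dark |= (t >= e.onset) & (t < e.offset)
        labels = ("subjective night", "subjective day")
    tbm = series.tb_masked()
    ok = np.isfinite(tbm)
    dn, ln_ = dark & ok, (~dark) & ok
    return PhaseSummary(
        dark_counts=float(series.lma[dark].sum()),
        light_counts=float(series.lma[~dark].sum()),
        dark_tb=float(tbm[dn].mean()) if dn.any() else np.nan,
        light_tb=float(tbm[ln_].mean()) if ln_.any() else np.nan,
        n_dark_bins=int(dn.sum()),
        n_light_bins=int(ln_.sum()),
        labels=labels,
    )
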