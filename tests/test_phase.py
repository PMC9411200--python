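"""Free-running period, phase shifts, re-entrainment and FAA."""

from dataclasses import replace

import numpy as np
import pytest

from chronotel import (
    DailyEpisode,
    LightPulse,
    LightSchedule,
    LightSegment,
    activity_midpoint,
    default_scenario,
    detect_episodes,
    faa,
    fit_tau,
    make_preset,
    phase_shift_type2,
    reentrainment_days,
    simulate_cohort,
    simulate_subject,
)
from conftest import make_square_series


def line_episodes(tau, n=5, start=0.0):
    return [DailyEpisode(i, start + tau * i, start + tau * i + 10.0, 10.0)
            for i in range(n)]


class TestFitTau:
    @pytest.mark.parametrize("tau", [20.5, 23.7, 24.1, 27.5])
    def test_exact_on_noiseless_onsets(self, tau):
        fit = fit_tau(line_episodes(tau))
        assert fit.tau == pytest.approx(tau, abs=1e-10)
        assert fit.rms_error == pytest.approx(0.0, abs=1e-9)

    def test_entrained_onsets_give_24(self):
        fit = fit_tau(line_episodes(24.0))
        assert fit.tau == pytest.approx(24.0)

    def test_dd_preset_recovery(self, dd_schedule):
        cohort = simulate_cohort(["GF-DD"], 6, base_seed=5, n_days=11)
        errs = []
        for series, truth in cohort:
            eps = detect_episodes(series, dd_schedule)
            fit = fit_tau(eps)
            errs.append(abs(fit.tau - truth.params.tau))
        assert np.mean(errs) < 0.02

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ValueError):
            fit_tau(line_episodes(24.0, n=2))

    def test_out_of_band_slope_flagged(self):
        fit = fit_tau([DailyEpisode(i, 30.0 * i, 30.0 * i + 10, 10.0)
                       for i in range(4)])
        assert not fit.accepted


def dd_with_pulse(pulse_t, label, days=16):
    return LightSchedule(
        segments=[LightSegment("DD", days=days)], start_clock=6.0,
        reference_lights_off_h=-12.0,
        pulses=[LightPulse(pulse_t, 15.0, label)],
    )


class TestPhaseShiftType2:
    def test_uniform_delay_recovered_exactly(self):
        pre = line_episodes(24.2, n=5, start=12.0)
        # post onsets uniformly 1.0 h later than the pre-pulse projection
        post = [DailyEpisode(5 + i, 12.0 + 24.2 * (5 + i) + 1.0,
                             12.0 + 24.2 * (5 + i) + 11.0, 10.0)
                for i in range(10)]
        res = phase_shift_type2(pre, post, pulse_time=12.0 + 24.2 * 4 + 3.0)
        assert res.shift == pytest.approx(-1.0, abs=1e-9)
        assert res.n_post_onsets == 7

    def test_null_shift_on_unperturbed_free_run(self, dd_schedule):
        for preset in ("SPF-DD", "GF-DD"):
            cfg = replace(make_preset(preset), seed=31)
            series, _ = simulate_subject(cfg, dd_schedule)
            eps = [e for e in detect_episodes(series, dd_schedule)
                   if e.detected]
            t_cut = eps[4].onset + 3.0
            pre = [e for e in eps if e.onset < t_cut]
            post = [e for e in eps if e.onset > t_cut]
            res = phase_shift_type2(pre, post, pulse_time=t_cut,
                                    transients_omitted=0, max_post_onsets=7)
            assert abs(res.shift) <= 0.25    # within ~2 detection bins

    @pytest.mark.parametrize("pzt,expected", [(15.0, -1.0), (22.0, 0.5)])
    def test_programmed_prc_recovery(self, pzt, expected):
        shifts = []
        for seed in range(20):
            pulse_t = 4 * 24 + pzt
            light = dd_with_pulse(pulse_t, f"pZT{pzt:.0f}")
            cfg = replace(make_preset("SPF-DD"), seed=400 + seed)
            series, truth = simulate_subject(cfg, light)
            eps = [e for e in detect_episodes(series, light) if e.detected]
            pre = [e for e in eps if e.onset < pulse_t]
            post = [e for e in eps if e.onset > pulse_t]
            res = phase_shift_type2(pre, post, pulse_time=pulse_t,
                                    pulse_pzt=pzt)
            assert truth.pulse_shifts[f"pZT{pzt:.0f}"] == expected
            shifts.append(res.shift)
        assert np.mean(shifts) == pytest.approx(expected, abs=0.2)

    def test_insufficient_post_onsets_rejected(self):
        pre = line_episodes(24.0, n=4)
        post = line_episodes(24.0, n=5, start=24.0 * 4)
        with pytest.raises(ValueError):
            phase_shift_type2(pre, post, pulse_time=90.0)


def jetlag_schedule(baseline_days=5, post_days=15, shift_h=6.0):
    return LightSchedule(segments=[
        LightSegment("LD", days=baseline_days, lights_on=6.0, lights_off=18.0),
        LightSegment("LD", days=post_days, lights_on=6.0 - shift_h,
                     lights_off=18.0 - shift_h),
    ], start_clock=6.0)


def jetlag_episodes(rate, seed=0, jitter=0.0):
    light = jetlag_schedule()
    cfg = replace(make_preset("SPF-LD"), reentrain_rate=rate, seed=seed,
                  onset_jitter_sd=jitter)
    series, truth = simulate_subject(cfg, light)
    return series, detect_episodes(series, light)


class TestReentrainment:
    def test_criterion_is_95_percent_of_shift(self):
        _, eps = jetlag_episodes(1.5)
        res = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
        assert res.criterion_fraction == pytest.approx(0.95)

    @pytest.mark.parametrize("rate", [0.5, 1.0, 1.5, 2.0, 3.0])
    def test_days_equal_closed_form_under_linear_relaxation(self, rate):
        _, eps = jetlag_episodes(rate, seed=3)
        res = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
        assert res.days_to_criterion == int(np.ceil(5.7 / rate))

    def test_immediate_shift_is_day_one(self):
        # onsets jump the full 6 h on the first post-shift day and hold
        _, eps = jetlag_episodes(24.0)
        res = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
        assert res.days_to_criterion == 1

    def test_monotone_in_reentrain_rate(self):
        days = []
        for rate in (0.5, 1.0, 1.5, 3.0):
            _, eps = jetlag_episodes(rate, seed=8, jitter=0.05)
            res = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
            days.append(res.days_to_criterion)
        assert all(a >= b for a, b in zip(days, days[1:]))

    def test_never_met_reports_sentinel(self):
        _, eps = jetlag_episodes(0.05)
        res = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
        assert res.days_to_criterion is None
        assert not res.reentrained
        assert res.days_observed > 0

    def test_midpoint_basis_agrees_within_a_day(self):
        for seed in range(6):
            series, eps = jetlag_episodes(1.0, seed=seed, jitter=0.05)
            mids = activity_midpoint(series, eps)
            r_on = reentrainment_days(eps, 6.0, 0.3, shift_time=120.0)
            r_mid = reentrainment_days(eps, 6.0, 0.3, basis="midpoint",
                                       shift_time=120.0, midpoints=mids)
            assert abs(r_on.days_to_criterion
                       - r_mid.days_to_criterion) <= 1


class TestActivityMidpoint:
    def test_square_wave_symmetric_midpoint(self, ld_schedule):
        s = make_square_series(n_days=4, on_h=12.0, off_h=24.0, bin_width=6.0)
        eps = detect_episodes(s, ld_schedule)
        mids = activity_midpoint(s, eps)
        det = [m for e, m in zip(eps, mids) if e.detected]
        for e, m in zip([e for e in eps if e.detected], det):
            # active 18:00-06:00 clock = t 12-24 per day: midpoint at t=18
            assert m - 24.0 * e.cycle_index == pytest.approx(18.0, abs=0.15)

    def test_point_mass_midpoint(self, ld_schedule):
        s = make_square_series(n_days=4, on_h=12.0, off_h=24.0, bin_width=6.0)
        # concentrate all activity at one bin inside the episode
        lma = np.zeros_like(s.lma)
        per_day = 240
        for d in range(4):
            lma[d * per_day + 140] = 50.0    # t = 14.0 h into the day
        eps = detect_episodes(s, ld_schedule)
        s2 = replace(s, lma=lma)
        mids = activity_midpoint(s2, eps)
        for e, m in zip(eps, mids):
            if e.detected:
                assert m - 24.0 * e.cycle_index == pytest.approx(14.05,
                                                                 abs=0.051)

    def test_undetected_day_missing(self):
        s = make_square_series(n_days=4)
        eps = [DailyEpisode(0, np.nan, np.nan, np.nan, detected=False)]
        assert np.isnan(activity_midpoint(s, eps)[0])


class TestFAA:
    def test_uniform_activity_gives_window_share(self):
        light, feeding, _ = default_scenario("SPF-RF")
        s = make_square_series(n_days=19, high=5.0, low=5.0, bin_width=6.0)
        res = faa(s, feeding, light)
        for day, frac in res.faa_fraction.items():
            assert frac == pytest.approx(3.0 / 24.0)

    def test_all_activity_in_window_gives_one(self):
        light, feeding, _ = default_scenario("SPF-RF")
        n = 19 * 240
        t = np.arange(n) * 0.1
        zt = np.mod(t, 24.0)      # start_clock 6, lights on 6: t0 is ZT0
        lma = np.where((zt >= 5.0) & (zt < 8.0), 10.0, 0.0)
        s = make_square_series(n_days=19, bin_width=6.0)
        s = replace(s, lma=lma)
        res = faa(s, feeding, light)
        for day in feeding.days:
            assert res.faa_fraction[day] == pytest.approx(1.0)

    def test_scale_invariance_and_conservation(self, ld_schedule):
        light, feeding, _ = default_scenario("GF-RF")
        cfg = replace(make_preset("GF-RF"), seed=77)
        series, _ = simulate_subject(cfg, light, feeding=feeding)
        r1 = faa(series, feeding, light)
        r2 = faa(replace(series, lma=series.lma * 3.0), feeding, light)
        for d in r1.faa_fraction:
            assert r1.faa_fraction[d] == pytest.approx(r2.faa_fraction[d])

    def test_day_types_labelled_from_schedule(self):
        light, feeding, _ = default_scenario("SPF-RF")
        s = make_square_series(n_days=19, high=5.0, low=5.0)
        res = faa(s, feeding, light)
        assert res.day_type[3] == "training"
        assert res.day_type[15] == "adlib"
        assert res.day_type[18] == "retention"

    def test_programmed_two_fold_contrast_recovered(self):
        light, feeding, _ = default_scenario("SPF-RF")
        ratios = []
        for rep in range(10):
            cohort = simulate_cohort(["SPF-RF", "GF-RF"], 4,
                                     base_seed=900 + rep)
            by = {"SPF-RF": [], "GF-RF": []}
            for series, _ in cohort:
                res = faa(series, feeding, light)
                by[series.group_label].append(res.on_days("retention")[-1])
            ratios.append(np.mean(by["GF-RF"]) / np.mean(by["SPF-RF"]))
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.3)

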