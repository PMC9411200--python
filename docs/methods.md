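# Methods

This note documents the models and procedures implemented in chronotel, the
parameter choices that matter, and what the synthetic-recovery tests do and
do not establish.

## Time conventions

Zeitgeber time is the standard one: ZT0 = lights-on, ZT12 = lights-off in a
12L:12D photocycle. In constant darkness (DD) times are *projected* ZT
(pZT), extrapolated at exactly 24.0 h/cycle from the last lights-off. A
τ-corrected projection is deliberately not used: pulse phases are named
relative to the prior photocycle, and animals are pulsed within ~2 cycles
of release into DD, where the accumulated τ drift (< 1 h for murine τ) is
below the pulse-timing resolution of the protocols represented here.
Internally all times are hours from the schedule origin; the CSV dialect
carries ISO-8601 timestamps.

Missing T_b samples are masked, never interpolated; masked bins are
excluded from every downstream mean. A day is unusable when more than 5%
of it is masked (conservative default; keeps per-day means unbiased at the
cost of discarding days with logger dropouts).

## Synthetic telemetry model

The generator is intentionally the *simplest* process with the statistical
structure the analyses assume, not a mechanistic oscillator network.

**Phase track.** Per-cycle activity onsets follow three regimes: under LD,
onset = lights-off + `onset_delay`; under DD, successive onsets advance by
τ; after a photocycle shift of S h the deviation from the new steady state
shrinks by `reentrain_rate` per day until exhausted (linear relaxation,
capped — this makes the expected days-to-criterion for a 6-h advance the
closed form ceil(5.7 / rate)); a 15-min light pulse at pZT p applies the
programmed phase-response value prc(p) once (advance positive), after
which free-running drift resumes. Cycle-to-cycle Gaussian onset jitter
(`onset_jitter_sd`) shifts whole episodes, so ground-truth α is exact by
construction (offset − onset every cycle).

**Activity.** The envelope is a square wave of width `alpha_true` with
logistic edges whose 10–90% rise spans `ramp_min` (default 12 min —
activity onset in mice is abrupt at 6-min actogram resolution). Per-bin
counts are Poisson with rate envelope·rate_active + (1 −
envelope)·rate_rest, scaled to bin width. Counts are device-specific in
real telemetry, so the absolute scale is arbitrary and every analysis is
required (and tested) to be scale-invariant; defaults are 20 and 1 counts
per 6-min bin.

**Restricted feeding.** On feeding-schedule days a rectangular
food-anticipatory component occupies the 3 h before mealtime. Its expected
share of the day's counts builds as a saturating exponential over training
days, f_d = asymptote·(1 − e^(−d/τ_FAA)) with τ_FAA = 3 days (FAA is
reported to emerge over several days; no functional form is established,
so the simplest saturating law is used), and holds at the trained level
through ad-lib and deprivation (retention) days. The extra counts are
sized as B·f/(1 − f) against the base expectation B, so the component
carries exactly the fraction f of the day's expected total.

**Body temperature.** tb = tb_base + tb_circ_amp·envelope +
tb_act_coupling·(30-min moving average of counts) + N(0, tb_noise_sd),
with defaults 36.5 °C, 1.0 °C, 0.03 °C/count and 0.15 °C — typical murine
telemetry magnitudes.

**Cohorts.** Subject seeds spawn deterministically from one base seed.
Between-subject variability is Gaussian on τ (SD 0.02 h), α (SD 0.2 h) and
tb_base (SD 0.06 °C) only; chosen so that group means over n = 8 resolve
the programmed contrasts at the tolerances used in the recovery tests,
which is also roughly what published group SEMs imply for inbred cohorts.

**Presets.** The named presets encode published group contrasts as model
parameters: SPF α 12.5 h vs GF 11.5 h under LD (GF onset 10 min later);
in DD, SPF α 12.7 h vs GF 11.9 h and GF τ = SPF τ + 0.04 h (2.4 min/day,
inside the reported 2–3 min/day window; the SPF base value 23.7 h is a
typical C57BL/6 figure since only the difference is published); GF-RF FAA
asymptote double SPF-RF (0.30 vs 0.15 of daily activity); high-fat-diet
variants shorten τ by 0.05 h, raise rest-phase T_b by 0.45 °C (midpoint of
the reported 0.3–0.6 °C, implemented as +0.45 on baseline and −0.45 on the
circadian amplitude so the active-phase peak is unchanged), halve the FAA
asymptote and speed re-entrainment; the conventionalized (ex-GF) preset
equals SPF except that it keeps the GF baseline-temperature deficit.
Expected daily totals are equalized across groups (active-phase rate
scales inversely with α) because total daily activity does not differ
between the groups being modeled; this also keeps the activity-coupled
T_b term balanced. The GF tb_base is set so the *designed 24-h mean* T_b
contrast is exactly 0.25 °C: the published contrast is a whole-day mean
difference, and a shorter α by itself lowers the 24-h mean through the
envelope term by amp·Δα/24, so the baseline offset absorbs the remainder.
The phase-response table maps pZT15 → −1.0 h (delay) and pZT22 → +0.5 h
(advance), the canonical early-/late-subjective-night geometry at
magnitudes typical for 15-min ~400-lx pulses in mice.

## Episode detection

Detection runs on 6-min re-binned data smoothed with a 3-bin centered
moving average. Each cycle's window spans one expected period starting 6 h
before the expected onset (lights-off in LD; previous detected onset +
expected period in DD). The activity threshold is threshold_frac ×
(P90 − P10) + P10 of that cycle's smoothed series; for T_b the threshold
is the midpoint of the cycle's P10/P90 (half-maximum of the nightly
elevation). An onset is the first bin in the search window that is itself
supra-threshold, has ≥ run_on of the following 2·run_on bins
supra-threshold, and ≥ run_off immediately preceding bins sub-threshold;
the offset applies the same rule in reversed time. Cycles with no
qualifying bin are flagged undetected and excluded from summaries (there
is no manual-correction step; exclusion counts are reported instead).

Defaults: run_on 6, run_off 4, search half-width 6 h, threshold_frac
0.35. The threshold fraction was fixed by recovery calibration on
simulator fixtures across α ∈ {10…13} h: a low fraction (e.g. 0.2)
systematically widens α by ~0.2 h because the crossing of a sigmoid edge
at 20% of amplitude precedes the envelope midpoint, while 0.35 balances
that bias against the bin-start/bin-end reporting convention (mean
absolute α error 0.06 h on the calibration grid). The commercial
implementations of this operator are undocumented, so numerical equality
with any product is not claimed — only ground-truth recovery.

Onset variability in LD is the sample SD of onset clock times after
unwrapping across midnight via the cycle index. Onset error in DD is the
RMS residual around the τ regression line (population normalization, as a
goodness-of-fit figure rather than an inferential SD).

## Rhythm metrics

**Lomb–Scargle.** Classical Scargle normalization: the data are mean
subtracted and PN(p) equals the explained sum of squares of the
least-squares sinusoid at trial period p divided by twice the sample
variance — the tests assert this equivalence against a brute-force
regression oracle at 1e−6. The period grid spans 20–28 h at an
oversampling factor (default 4) relative to the 1/span Fourier spacing;
the peak is therefore resolved to one grid step. Significance uses the
independent-frequencies approximation PN_sig = ln(M/FAP) with M =
span·Δf and FAP 0.001. The approximation is crude for oversampled grids
but matches the conventional threshold usage; a permutation alternative
can be built from `lomb_scargle` directly by shuffling bins.

**NPCRA.** The mean 24-h profile is scanned with circularly wrapped
windows: M = best 10-h window mean, L = worst 5-h window mean, relative
amplitude (M − L)/(M + L). The 10/5 window convention is the established
non-parametric choice; both window lengths are arguments. The absolute
difference M − L is also reported because count units are device-specific.

**Profiles and phase summaries.** Folding uses floor((t mod P)/w) bin
assignment, exact for P = 24 h on the native grid; per-bin means exclude
masked bins, and the identity Σ(bin mean × bin n) = total counts is
asserted. In LD the photocycle splits the day (scotophase ZT12–24); in DD
the detected episodes supply subjective night per cycle.

## Phase analysis

τ is the OLS slope of onset time (absolute hours) on cycle index — exact
on noiseless periodic onsets for any period, and recovered within 0.02 h
on DD preset cohorts. Fits outside (20, 28) h are flagged rather than
returned as accepted.

Type II phase shifts: the pre-pulse onsets are regressed and extrapolated
to the pulse cycle (this extrapolation also defines the "pulse-day onset"
when the pulse disturbs that night's activity — the projection from the
undisturbed pre-pulse rhythm is the only phase estimate available in that
case); the post-pulse rhythm is regressed on up to 7 onsets after omitting
3 transient cycles and extrapolated back. Shift = pre − post at the pulse
cycle; advances positive. Null calibration on unperturbed free runs
returns 0 within ~2 detection bins.

Jet-lag re-entrainment measures each post-shift day's phase against the
*mean pre-shift onset clock time* (not a τ-corrected projection — the
animals modeled are entrained, τ ≈ 24 h, and the criterion is a clock-time
displacement). Criterion: first post-shift day with achieved shift ≥
6 − 0.3 h, by default confirmed by the following day (a 2-day stability
guard against sporadic single-day advances); the raw first crossing is
available by flag. Day numbers come from cycle indices, so a cycle the
detector missed leaves a gap instead of renumbering subsequent days.
Midpoint-based re-entrainment uses the activity center of mass within
onset→offset and agrees with the onset basis within a day on simulated
fixtures.

FAA per scheduled day = counts in the 3 h before the actual (training) or
expected (ad-lib/retention) mealtime divided by that ZT-day's total; days
with zero counts yield a missing value. The restricted-feeding protocol
generator reproduces the standard ramp (day 1 ZT8–16, day 2 ZT8–14, then
ZT8–12), two ad-lib days, and a 48-h deprivation retention trial;
retention endpoints are read on deprivation day 2. Note the recovered
GF/SPF retention ratio sits slightly below the programmed asymptote ratio
of 2.0 (~1.93 at default rates) because the anticipation window also
carries rest-phase baseline counts in both groups; this is a property of
the measure, not a bias in the estimator, and lies well inside the ±0.3
acceptance band.

## Statistics

Outlier screening is a single pass per measure, pooled across groups:
values beyond k = 3 sample SDs of the pooled mean are removed (~0.27% of
Gaussian data; the rule is near-idempotent at small n). Pooling across
groups is the conservative reading of a "sample mean" rule — per-group
screening with group-specific SDs removes more points. Two-sample tests
default to the pooled-variance t (matching the legacy analyses these
pipelines descend from) with Welch by flag; Hedges' g applies the
(1 − 3/(4·df − 1)) small-sample correction and converges to Cohen's d as
df → ∞. Factorial ANOVA is fixed-effects OLS with Type II sums of squares
(no interaction-driven contamination of main effects in unbalanced
layouts) via statsmodels, verified against a nested-model residual-SS
oracle. No multiple-testing correction is applied, by design parity with
the analyses modeled. The battery merges cohorts only when a cohort
factor is non-significant, via the same ANOVA machinery.

## Problem sizes and determinism

Default validation scenarios use the cohort sizes the endpoints are
designed around: n = 8/group, 12 LD or 11 DD days at 1-min bins for the
entrainment/DD endpoints; 20 seeded cohorts of n = 4/group for the FAA
ratio; jet-lag and pulse fixtures use 5 baseline + 15 post-shift days and
16 DD days respectively. All randomness flows through
numpy `SeedSequence` spawning, so identical configurations are
bit-reproducible across platforms.

## What recovery tests do not show

The simulator omits ultradian bout structure, masking by light,
cage-change artifacts, transient cycles after pulses (shifts are applied
instantaneously, so the 3-cycle transient omission is exercised as a
windowing convention, not as transient rejection), aftereffects of
entrainment on τ, and any microbiome dynamics. Passing recovery therefore
establishes that the estimators are unbiased and correctly scaled for
data with the assumed structure — not that detection parameters are
optimal for any particular logger or strain, which is why all of them are
exposed as configuration.
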