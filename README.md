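# chronotel

Circadian analysis battery for rodent telemetry (locomotor activity + core
body temperature), with a synthetic telemetry simulator for validation by
parameter recovery.

## What this is for

Chronobiology experiments record activity counts and body temperature (T_b)
from implanted transmitters at 1-min resolution, then reduce weeks of
telemetry to a standard panel of endpoints: daily activity **onsets and
offsets** and the active-phase duration **α**; the free-running period
**τ** in constant darkness (slope of a regression through successive
onsets); **onset variability** under entrainment (SD of successive onset
clock times) and **onset error** in DD (RMS deviation from the τ
regression line); **Lomb–Scargle periodogram power** (PN) and the
non-parametric **M10/L5 relative amplitude**; **Aschoff Type II phase
shifts** to discrete light pulses; days to re-entrain after a simulated
**jet lag** (6-h photocycle advance, criterion 6 ± 0.3 h = 95% of the
shift); and **food-anticipatory activity** (FAA) under restricted feeding —
the fraction of a day's activity in the 3 h before mealtime. Historically
most of these reductions live inside closed commercial software; chronotel
is an open, tested implementation of the full panel, plus the group-level
statistics used with it (± 3 SD outlier exclusion, pooled-variance t-tests
with Hedges' *g*, two-way Type II ANOVA).

Because real telemetry has no ground truth, the package ships a simulator:
an entrainable phase track (onsets lock to lights-off under LD, drift at
τ − 24 h/day in DD, relax linearly after schedule shifts, respond to
programmed phase-response values for light pulses) drives a square activity
envelope with sigmoid edges; counts are Poisson, and T_b adds a baseline,
an envelope-locked circadian component, activity coupling and Gaussian
noise. Named presets (`SPF-LD`, `GF-LD`, `EXGF-LD`, `SPF-DD`, `GF-DD`,
`SPF-RF`, `GF-RF`, `SPF-HFD`, `GF-HFD`) encode published group contrasts
for germ-free (GF) versus specific-pathogen-free (SPF) mice — compressed α,
a 2–3 min/day longer τ, ~0.25 °C hypothermia, two-fold FAA — so every
analysis stage is verifiable by recovering what the generator put in.

## Worked example

Simulate an SPF vs GF cohort (n = 8 each, 12 days of 12L:12D) and run the
battery:

```python
from chronotel import run_battery

cfg = {"scenario": {"groups": [{"preset": "SPF-LD", "n": 8},
                               {"preset": "GF-LD", "n": 8}],
                    "seed": 7, "n_days": 12}}
out = run_battery(cfg, "run/")
print(out["tests"][["measure", "mean_a", "mean_b", "t", "df", "p",
                    "hedges_g"]].to_string(index=False))
```

which prints (abridged):

```
           measure  mean_a  mean_b      t  df         p  hedges_g
       alpha_lma_h   12.47   11.55  18.98  14 2.184e-11     8.972
relative_amplitude  0.9105  0.9168 -3.625  14  0.002757    -1.714
       lsp_peak_pn    4084    4340 -11.25  14 2.122e-08     -5.32
        onset_sd_h 0.06549  0.0486   2.92  14   0.01119      1.38
        alpha_tb_h   12.39   11.46  19.27  14 1.773e-11     9.112
         mean_tb_c   37.06   36.83  10.73  14  3.87e-08     5.073
```

Reading this: detection recovers the programmed active-phase compression
(α_LMA 12.5 → 11.5 h and the matching T_b elevation), the GF group is
~0.23 °C cooler over 24 h, and its onsets are *more* precise under LD
(smaller onset SD), all with the t/df/p and Hedges' *g* the battery
computes after ± 3 SD outlier screening. The same pipeline is available
from the shell:

```bash
chronotel simulate --scenario study.yaml --out sim/
chronotel analyze  --config   study.yaml --out run/
chronotel report   --out run/
```

Library entry points mirror the pipeline stages: `simulate_cohort` /
`make_preset` (data), `detect_episodes` / `detect_tb_elevation` /
`alpha_summary` / `onset_variability_ld` (episodes), `lomb_scargle` /
`npcra_amplitude` / `daily_profile` / `phase_summary` (rhythm metrics),
`fit_tau` / `phase_shift_type2` / `reentrainment_days` / `faa` (phase
analysis), `exclude_outliers` / `two_sample_test` / `anova_factorial`
(statistics). Telemetry I/O uses a plain CSV dialect
(`timestamp,lma,tb`, ISO-8601 timestamps, `NA` for missing T_b);
schedules are plain YAML/JSON mappings.

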