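"""Group-level statistics and the end-to-end analysis battery.

Reproduces the legacy behavioral-statistics pipeline: single-pass +/- 3 SD
outlier exclusion pooled across groups, pooled-variance two-tailed t-tests
with bias-corrected Hedges' g, and two-way fixed-effects ANOVA (Type II sums
of squares for unbalanced layouts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .telemetry import TelemetrySeries, write_telemetry
from .simulate import GroundTruth, default_scenario, simulate_cohort
from .episodes import (
    DetectionParams,
    alpha_summary,
    detect_episodes,
    detect_tb_elevation,
    onset_variability_ld,
)
from .rhythms import lomb_scargle, npcra_amplitude, phase_summary
from .phase import faa, fit_tau

logger = logging.getLogger("chronotel")

__all__ = [
    "GroupTable",
    "StatResult",
    "exclude_outliers",
    "two_sample_test",
    "hedges_g",
    "anova_factorial",
    "run_battery",
]


@dataclass
class GroupTable:
    """One measure's per-subject values across groups."""

    measure_name: str
    data: pd.DataFrame            # columns: subject_id, group_label, value
    units: str = ""

    def __post_init__(self) -> None:
        need = {"subject_id", "group_label", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"GroupTable needs columns {sorted(need)}")
        if self.data["subject_id"].duplicated().any():
            raise ValueError("one value per subject per measure")

    def values(self, group: str) -> np.ndarray:
        return self.data.loc[self.data["group_label"] == group,
                             "value"].to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group_label"]))


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: float
    p_value: float
    effect_size_g: float = np.nan
    sum_sq: float = np.nan            # populated for ANOVA terms
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def exclude_outliers(
    table: GroupTable, k: float = 3.0
) -> tuple[GroupTable, dict]:
    """Single-pass outlier exclusion: values more than ``k`` sample SDs from
    the pooled (across-group) mean of the measure are removed. With k = 3 on
    Gaussian data this removes about 0.3% of points."""
    v = table.data["value"].to_numpy(dtype=float)
    if len(v) < 4:
        raise ValueError("need >= 4 values per measure")
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        keep = np.ones(len(v), dtype=bool)
    else:
        keep = np.abs(v - mu) <= k * sd
    removed = table.data.loc[~keep, "subject_id"].tolist()
    out = GroupTable(table.measure_name, table.data.loc[keep].reset_index(drop=True),
                     table.units)
    report = {
        "measure": table.measure_name,
        "excluded_ids": removed,
        "n_excluded": len(removed),
        "fraction_excluded": len(removed) / len(v),
        "mean": float(mu),
        "sd": float(sd),
        "k": k,
    }
    return out, report


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Bias-corrected standardized mean difference,
    g = d * (1 - 3/(4*df - 1)) with d the pooled-SD Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return 0.0 if np.isclose(a.mean(), b.mean()) else np.inf
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return float(d * (1.0 - 3.0 / (4.0 * df - 1.0)))


def two_sample_test(
    a: np.ndarray, b: np.ndarray, welch: bool = False,
    name: str = "t-test",
) -> StatResult:
    """Two-tailed two-sample t-test (pooled variance by default, Welch by
    flag) with Hedges' g."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    stat = float(res.statistic)
    if not np.isfinite(stat):
        logger.warning("%s: zero pooled variance with unequal means", name)
    return StatResult(
        test_name=name, statistic=stat, df=df,
        p_value=float(res.pvalue), effect_size_g=hedges_g(a, b),
    )


def anova_factorial(
    table: GroupTable, factors: tuple[str, str]
) -> dict[str, StatResult]:
    """Two-way fixed-effects ANOVA with Type II sums of squares.

    ``table.data`` must carry one column per factor. Returns main effects
    and the interaction keyed by term name.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    df = table.data.copy()
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor column {f!r} missing")
        df[f] = df[f].astype(str)
    counts = df.groupby([fa, fb], observed=True).size().unstack(fill_value=0)
    if (counts == 0).any().any():
        empties = [(i, c) for i in counts.index for c in counts.columns
                   if counts.loc[i, c] == 0]
        raise ValueError(f"empty cell(s) in {fa} x {fb} layout: {empties}")
    model = smf.ols(f"value ~ C({fa}) * C({fb})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out: dict[str, StatResult] = {}
    keymap = {f"C({fa})": fa, f"C({fb})": fb,
              f"C({fa}):C({fb})": f"{fa}:{fb}"}
    for row, key in keymap.items():
        out[key] = StatResult(
            test_name=f"ANOVA {key}",
            statistic=float(aov.loc[row, "F"]),
            df=float(aov.loc[row, "df"]),
            p_value=float(aov.loc[row, "PR(>F)"]),
            sum_sq=float(aov.loc[row, "sum_sq"]),
        )
    return out


# ---------------------------------------------------------------------------
# battery runner
# ---------------------------------------------------------------------------

def _measures_for_subject(series, truth, preset: str,
                          params: DetectionParams) -> dict[str, float]:
    """All per-subject scalar endpoints the preset's scenario supports."""
    from .simulate import default_scenario

    light, feeding, _ = default_scenario(preset)
    out: dict[str, float] = {}
    episodes = detect_episodes(series, light, params)
    asum = alpha_summary(episodes)
    out["alpha_lma_h"] = asum["mean"]
    out["n_detected"] = asum["n"]
    out["total_counts_per_day"] = float(series.lma.sum() / (series.duration_h / 24.0))
    amp = npcra_amplitude(series)
    out["relative_amplitude"] = amp.relative_amplitude
    lsp = lomb_scargle(series)
    out["lsp_peak_pn"] = lsp.peak_pn
    out["lsp_peak_period_h"] = lsp.peak_period

    is_dd = not light.lights_off_events().size
    if is_dd:
        fit = fit_tau(episodes)
        out["tau_h"] = fit.tau
        out["onset_error_h"] = fit.rms_error
        tb_eps = detect_tb_elevation(series, light, params)
        out["alpha_tb_h"] = alpha_summary(tb_eps)["mean"]
        ps = phase_summary(series, light, episodes)
    else:
        out["onset_sd_h"] = onset_variability_ld(episodes)
        tb_eps = detect_tb_elevation(series, light, params)
        out["alpha_tb_h"] = alpha_summary(tb_eps)["mean"]
        ps = phase_summary(series, light)
    out["mean_tb_c"] = ps.mean_tb
    out["dark_counts"] = ps.dark_counts
    out["light_counts"] = ps.light_counts
    out["dark_tb_c"] = ps.dark_tb
    out["light_tb_c"] = ps.light_tb

    if feeding is not None:
        fr = faa(series, feeding, light)
        retention = fr.on_days("retention")
        if retention:
            out["faa_retention_day2"] = retention[-1]
        training = fr.on_days("training")
        if training:
            out["faa_training_mean"] = float(np.nanmean(training))
    return out


def run_battery(
    config: dict | str | Path,
    out_dir: str | Path,
    make_plots: bool = False,
) -> dict:
    """Execute the full analysis battery for a simulated-cohort scenario.

    ``config`` is a mapping (or path to a YAML/JSON file) like::

        scenario:
          groups: [{preset: SPF-LD, n: 8}, {preset: GF-LD, n: 8}]
          seed: 7
        detection: {threshold_frac: 0.2}

    Writes per-subject telemetry + measures CSVs, group tables, test results
    and a run log; per-subject failures are recorded and skipped.
    """
    if not isinstance(config, dict):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scen = config["scenario"]
    seed = int(scen.get("seed", 0))
    params = DetectionParams(**config.get("detection", {}))
    n_days = scen.get("n_days")

    rows, failures = [], []
    subjects = []
    for gi, g in enumerate(scen["groups"]):
        preset, n = g["preset"], int(g["n"])
        cohort = simulate_cohort([preset], n,
                                 base_seed=(seed * 1009 + gi) % 2**31,
                                 n_days=n_days)
        for series, truth in cohort:
            subjects.append((preset, series, truth))

    for preset, series, truth in subjects:
        try:
            m = _measures_for_subject(series, truth, preset, params)
            m["subject_id"] = series.subject_id
            m["group_label"] = preset
            rows.append(m)
        except Exception as exc:       # battery continues for the rest
            logger.error("subject %s failed: %s", series.subject_id, exc)
            failures.append({"subject_id": series.subject_id, "error": str(exc)})

    measures = pd.DataFrame(rows)
    measures.to_csv(out_dir / "measures.csv", index=False)

    groups = list(dict.fromkeys(p for p, _, _ in subjects))
    tests, exclusions = [], []
    numeric_cols = [c for c in measures.columns
                    if c not in ("subject_id", "group_label")]
    for col in numeric_cols:
        sub = measures[["subject_id", "group_label", col]].dropna()
        if len(sub) < 4 or sub[col].nunique() < 2:
            continue
        gt = GroupTable(col, sub.rename(columns={col: "value"}))
        gt, report = exclude_outliers(gt, k=3.0)
        exclusions.append(report)
        if len(groups) >= 2:
            a = gt.values(groups[0])
            b = gt.values(groups[1])
            if len(a) >= 2 and len(b) >= 2:
                res = two_sample_test(a, b,
                                      name=f"{col}: {groups[0]} vs {groups[1]}")
                tests.append({
                    "measure": col, "group_a": groups[0], "group_b": groups[1],
                    "mean_a": a.mean(), "mean_b": b.mean(),
                    "t": res.statistic, "df": res.df, "p": res.p_value,
                    "hedges_g": res.effect_size_g,
                })
    pd.DataFrame(tests).to_csv(out_dir / "group_tests.csv", index=False)
    with open(out_dir / "exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=1)

    if make_plots:
        _write_actograms(subjects, out_dir)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    log = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
        "n_subjects": len(subjects),
        "failures": failures,
        "groups": groups,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return {"measures": measures, "tests": pd.DataFrame(tests),
            "exclusions": exclusions, "log": log}


def _write_actograms(subjects, out_dir: Path) -> None:
    """Double-plotted (48-h row) actogram PNGs for visual QC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for preset, series, _ in subjects:
        per_day = int(round(24 * 60 / series.bin_width))
        n_days = series.n_bins // per_day
        if n_days < 2:
            continue
        counts = series.lma[:n_days * per_day].reshape(n_days, per_day)
        fig, axes = plt.subplots(n_days - 1, 1, sharex=True,
                                 figsize=(8, 0.35 * n_days))
        if n_days - 1 == 1:
            axes = [axes]
        top = np.percentile(counts, 99) or 1
        x = np.arange(2 * per_day) * series.bin_width / 60.0
        for d, ax in enumerate(axes):
            row = np.concatenate([counts[d], counts[d + 1]])
            ax.fill_between(x, np.clip(row, 0, top), step="mid", color="k")
            ax.set_yticks([])
            ax.set_ylabel(str(d), rotation=0, fontsize=6, va="center")
        axes[-1].set_xlabel("hours (double-plotted)")
        fig.suptitle(series.subject_id, fontsize=8)
        fig.savefig(out_dir / f"actogram_{series.subject_id}.png", dpi=110)
        plt.close(fig)
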