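"""Statistical analysis of the cooling experiment.

Reproduces the study's analysis of the 4-animal cohort: 60 s moving
averages of the 1 Hz recordings, per-animal baseline and 60-min values,
group means with sample SDs, cooling rates as endpoint differences per
hour, Shapiro–Wilk normality checks, and two-tailed paired Student's
t tests on the baseline vs 60-min values.  A comparison routine flags,
point by point, whether a simulated trace falls inside the cohort's
95 % confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsReport",
    "moving_average",
    "summarize_cohort",
    "paired_t",
    "shapiro_wilk",
    "compare_sim_to_experiment",
    "DegenerateSampleError",
]

#: default moving-average window (s); the study smooths 1 Hz records
DEFAULT_WINDOW_S = 60.0
ALPHA = 0.05


class DegenerateSampleError(ValueError):
    """Raised when a test's sampling distribution is undefined (zero variance)."""


def moving_average(
    series: Sequence[float], window_s: float, sample_interval_s: float = 1.0
) -> np.ndarray:
    """Centered moving mean with trend-preserving edge handling.

    The window covers ``window_s`` seconds of a regularly sampled series
    (an odd number of points, so the window is symmetric).  At the
    boundaries the series is padded by odd (anti-symmetric) reflection
    about the end points, so constant series and linear ramps pass
    through unchanged — the smoothed endpoint of a ramp equals the raw
    endpoint, which keeps endpoint-difference cooling rates unbiased.
    Series shorter than a half-window fall back to truncated windows.
    A window of one sample is the identity.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    if window_s < sample_interval_s:
        raise ValueError("window_s must cover at least one sample")
    half = int(window_s / (2.0 * sample_interval_s))
    n = 2 * half + 1
    if half == 0:
        return x.copy()
    if x.size <= half:
        return (
            pd.Series(x).rolling(window=n, center=True, min_periods=1).mean().to_numpy()
        )
    left = 2.0 * x[0] - x[1: half + 1][::-1]
    right = 2.0 * x[-1] - x[-half - 1: -1][::-1]
    padded = np.concatenate([left, x, right])
    return np.convolve(padded, np.ones(n), mode="valid") / n


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, int, float]:
    """Two-tailed paired Student's t test.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` for the
    differences ``d = before - after``, ``df = n - 1`` and the two-tailed
    p-value from the t distribution.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before/after must be 1-D and of equal length")
    n = b.size
    if n < 2:
        raise ValueError("paired t test requires at least two pairs")
    d = b - a
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("differences have zero variance")
    t = float(np.mean(d)) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value (Royston's approximation)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro–Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro–Wilk p-value approximation is limited to n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StatsReport:
    """Cohort summary in the style of the study's Table 1 + Results text."""

    n: int
    window_s: float
    baseline_brain_C: list[float]
    baseline_body_C: list[float]
    final_brain_C: list[float]
    final_body_C: list[float]
    rate_brain_C_per_h: list[float]
    rate_body_C_per_h: list[float]
    baseline_brain_mean_C: float = 0.0
    baseline_brain_sd_C: float = 0.0
    baseline_body_mean_C: float = 0.0
    baseline_body_sd_C: float = 0.0
    rate_brain_mean_C_per_h: float = 0.0
    rate_brain_sd_C_per_h: float = 0.0
    rate_body_mean_C_per_h: float = 0.0
    rate_body_sd_C_per_h: float = 0.0
    shapiro: dict[str, tuple[float, float]] = field(default_factory=dict)
    paired: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    normality_flag: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def table(self) -> str:
        """Human-readable per-animal table with group summaries."""
        lines = [
            f"{'animal':>8} {'brain base':>11} {'brain 60min':>12} "
            f"{'body base':>11} {'body 60min':>12}",
        ]
        for k in range(self.n):
            lines.append(
                f"{k + 1:>8d} {self.baseline_brain_C[k]:>11.2f} "
                f"{self.final_brain_C[k]:>12.2f} {self.baseline_body_C[k]:>11.2f} "
                f"{self.final_body_C[k]:>12.2f}"
            )
        lines.append(
            f"baseline brain {self.baseline_brain_mean_C:.1f} "
            f"({self.baseline_brain_sd_C:.1f}) °C, "
            f"body {self.baseline_body_mean_C:.1f} ({self.baseline_body_sd_C:.1f}) °C"
        )
        lines.append(
            f"cooling rate brain {self.rate_brain_mean_C_per_h:.2f} "
            f"({self.rate_brain_sd_C_per_h:.2f}) °C/h, "
            f"body {self.rate_body_mean_C_per_h:.2f} "
            f"({self.rate_body_sd_C_per_h:.2f}) °C/h"
        )
        tb, dfb, pb = self.paired["brain"]
        tc, dfc, pc = self.paired["body"]
        lines.append(
            f"paired t (baseline vs 60 min): brain t={tb:.2f}, df={dfb}, p={pb:.4f}; "
            f"body t={tc:.2f}, df={dfc}, p={pc:.4f}"
        )
        return "\n".join(lines)


def summarize_cohort(records, window_s: float = DEFAULT_WINDOW_S) -> StatsReport:
    """Per-animal and group summaries of a cohort of 1 Hz recordings.

    ``records`` is a sequence of :class:`neckcool.synthetic_data.ExperimentRecord`.
    Baseline and 60-min values are the centered moving averages at the
    first and last samples; cooling rates are their difference per hour.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("at least two records are required")
    n_samples = {r.brain_C.size for r in records} | {r.body_C.size for r in records}
    if len(n_samples) != 1:
        raise ValueError(f"records of unequal length: {sorted(n_samples)}")

    base_brain, base_body, fin_brain, fin_body = [], [], [], []
    rate_brain, rate_body = [], []
    for r in records:
        dt = float(np.median(np.diff(r.time_s)))
        hours = (r.time_s[-1] - r.time_s[0]) / 3600.0
        for series, base, fin, rate in (
            (r.brain_C, base_brain, fin_brain, rate_brain),
            (r.body_C, base_body, fin_body, rate_body),
        ):
            sm = moving_average(series, window_s, sample_interval_s=dt)
            base.append(float(sm[0]))
            fin.append(float(sm[-1]))
            rate.append(float((sm[0] - sm[-1]) / hours))

    def sd(v):
        return float(np.std(v, ddof=1))

    def safe_shapiro(values):
        if np.std(values) == 0.0:        # degenerate: test undefined
            return (float("nan"), float("nan"))
        return shapiro_wilk(values)

    def safe_paired(before, after):
        try:
            return paired_t(before, after)
        except DegenerateSampleError:
            return (float("nan"), len(before) - 1, float("nan"))

    shapiro = {
        "baseline_brain": safe_shapiro(base_brain),
        "baseline_body": safe_shapiro(base_body),
        "diff_brain": safe_shapiro(np.subtract(base_brain, fin_brain)),
        "diff_body": safe_shapiro(np.subtract(base_body, fin_body)),
    }
    normality = all(p > ALPHA for _, p in shapiro.values() if not np.isnan(p))
    paired = {
        "brain": safe_paired(base_brain, fin_brain),
        "body": safe_paired(base_body, fin_body),
    }
    return StatsReport(
        n=len(records),
        window_s=window_s,
        baseline_brain_C=base_brain,
        baseline_body_C=base_body,
        final_brain_C=fin_brain,
        final_body_C=fin_body,
        rate_brain_C_per_h=rate_brain,
        rate_body_C_per_h=rate_body,
        baseline_brain_mean_C=float(np.mean(base_brain)),
        baseline_brain_sd_C=sd(base_brain),
        baseline_body_mean_C=float(np.mean(base_body)),
        baseline_body_sd_C=sd(base_body),
        rate_brain_mean_C_per_h=float(np.mean(rate_brain)),
        rate_brain_sd_C_per_h=sd(rate_brain),
        rate_body_mean_C_per_h=float(np.mean(rate_body)),
        rate_body_sd_C_per_h=sd(rate_body),
        shapiro=shapiro,
        paired=paired,
        normality_flag=normality,
    )


def compare_sim_to_experiment(
    trace,
    records,
    window_s: float = DEFAULT_WINDOW_S,
    decimate_s: float = 60.0,
    node_map: dict[str, str] | None = None,
) -> dict:
    """Fraction of time points at which the simulation sits inside the
    cohort's 95 % confidence interval.

    The cooling hour of ``trace`` (from its ``cooling_on`` phase mark) is
    aligned with the records' time axis; both are smoothed with the same
    moving average, decimated to ``decimate_s``, and at each grid point
    the cohort mean ± t-based 95 % CI is computed per channel
    (brain -> simulated head node, body -> simulated body node by
    default).
    """
    node_map = node_map or {"brain": "head", "body": "body"}
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("at least two records are required")

    t_on = trace.phase_marks.get("cooling_on", 0.0)
    t_rel = trace.times - t_on
    rec_t = records[0].time_s
    dt_rec = float(np.median(np.diff(rec_t)))
    step = max(1, int(round(decimate_s / dt_rec)))
    grid = rec_t[::step]
    if grid[-1] > t_rel[-1] + 1e-9 or grid[0] < t_rel[0] - 1e-9:
        raise ValueError("trace does not cover the records' time grid")

    dt_trace = float(np.median(np.diff(trace.times)))
    out: dict[str, dict] = {"grid_s": grid.tolist()}
    fractions = {}
    tcrit = float(sps.t.ppf(0.975, n - 1))
    for channel, node in node_map.items():
        rec_mat = np.vstack([
            moving_average(getattr(r, f"{channel}_C"), window_s, dt_rec) for r in records
        ])
        rec_dec = rec_mat[:, ::step]
        mean = rec_dec.mean(axis=0)
        half = tcrit * rec_dec.std(axis=0, ddof=1) / np.sqrt(n)
        sim_sm = moving_average(trace.series(node), window_s, dt_trace)
        sim_on_grid = np.interp(grid, t_rel, sim_sm)
        inside = np.abs(sim_on_grid - mean) <= half
        fractions[channel] = float(np.mean(inside))
        out[channel] = {
            "mean_C": mean.tolist(),
            "ci_halfwidth_C": half.tolist(),
            "simulated_C": sim_on_grid.tolist(),
            "inside": inside.tolist(),
        }
    out["fraction_inside"] = fractions
    return out
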