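"""Scoring: lagged cross-correlation, category bins, latency and connectivity.

Prediction quality is measured as the normalised cross-correlation between
the actual and predicted signal over integer-sample lags within a short
window (default +/-100 ms): both series are centred and scaled to unit
population variance over the full record, and the coefficient at lag ``k``
is the mean product over the overlapping segment scaled by the full length,

    r(k) = (1/n) * sum_t a_z(t) * p_z(t + k).

The maximum coefficient over the window is the headline number, binned as
'high' (r >= 0.7), 'moderate' (0.7 > r >= 0.5), 'weak' (0.5 > r >= 0.3) or
'very_weak' (r < 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SpikeRaster
from .span_core import convolve_train

__all__ = [
    "CrossCorrResult",
    "xcorr_lagged",
    "categorize",
    "smooth_signal",
    "smooth_population_activity",
    "score_predictions",
    "latency_report",
    "learning_curve",
    "connectivity_summary",
]


@dataclass
class CrossCorrResult:
    """Cross-correlation over lags plus its maximum and category."""

    lags_s: np.ndarray
    coefficients: np.ndarray
    r_max: float
    lag_at_max_s: float
    category: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags_s, "r": self.coefficients})


def categorize(r: float) -> str:
    """Bin a correlation coefficient into the standard four ranges."""
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    if r >= 0.7:
        return "high"
    if r >= 0.5:
        return "moderate"
    if r >= 0.3:
        return "weak"
    return "very_weak"


def xcorr_lagged(
    actual,
    predicted,
    sample_rate: float,
    max_lag_ms: float = 100.0,
) -> CrossCorrResult:
    """Normalised cross-correlation at every integer-sample lag in the window.

    Positive lag means the predicted series is shifted later relative to the
    actual one (``r(k)`` correlates ``actual(t)`` with ``predicted(t + k)``).
    Constant inputs have undefined correlation and raise.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be 1-D and equal length")
    max_lag = int(round(max_lag_ms / 1000.0 * sample_rate))
    if a.size < 2 * max_lag + 2:
        raise ValueError("signals too short for the requested lag window")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("undefined correlation: at least one signal is constant")
    az = (a - a.mean()) / np.std(a)
    pz = (p - p.mean()) / np.std(p)
    n = a.size
    lags = np.arange(-max_lag, max_lag + 1)
    full = np.correlate(pz, az, mode="full")  # index n-1+k = sum_t az[t] pz[t+k]
    coeffs = full[n - 1 + lags] / n
    imax = int(np.argmax(coeffs))
    r_max = float(coeffs[imax])
    return CrossCorrResult(
        lags_s=lags / sample_rate,
        coefficients=coeffs,
        r_max=r_max,
        lag_at_max_s=float(lags[imax] / sample_rate),
        category=categorize(r_max),
    )


def smooth_signal(x, sample_rate: float, window_ms: float = 50.0) -> np.ndarray:
    """Centred moving-average smoothing (edge-padded), window in ms."""
    x = np.asarray(x, dtype=float)
    w = max(int(round(window_ms / 1000.0 * sample_rate)), 1)
    if w == 1:
        return x.copy()
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(pad, kernel, mode="valid")


def smooth_population_activity(
    raster: SpikeRaster,
    tau_s_s: float,
    grid: np.ndarray,
    weights=None,
) -> np.ndarray:
    """Average alpha-convolved member activity: the predicted analog signal.

    ``weights`` (optional, one per member) weight each member's convolved
    train before averaging over the member count; this matches the readout
    neuron's average synaptic current.
    """
    grid = np.asarray(grid, dtype=float)
    if raster.n_channels == 0:
        return np.zeros_like(grid)
    if weights is None:
        weights = np.ones(raster.n_channels)
    weights = np.asarray(weights, dtype=float)
    acc = np.zeros_like(grid)
    for w, train in zip(weights, raster.trains):
        if w != 0.0:
            acc += w * convolve_train(train.times, tau_s_s, grid)
    return acc / raster.n_channels


def score_predictions(
    model,
    result,
    targets,
    max_lag_ms: float = 100.0,
    smooth_ms: float = 50.0,
    activity_tau_ms: float | None = None,
) -> pd.DataFrame:
    """Correlate each population's predicted activity with its actual target.

    The predicted analog signal is the population's average alpha-convolved
    member activity (kernel ``activity_tau_ms``, defaulting to the model's
    readout kernel); the actual signal is the moving-average-smoothed target
    channel.  Returns one row per target with ``r_max``, the lag at the
    maximum and the category; a population that never spiked gets ``r_max``
    of 0 and category ``undefined``.
    """
    sr = targets.sample_rate
    grid_s = np.arange(targets.n_samples) / sr
    tau_s = (activity_tau_ms if activity_tau_ms is not None else model.config.activity_tau)
    tau_s = tau_s / 1000.0
    rows = []
    for label in model.target_labels:
        actual = smooth_signal(targets.channel(label), sr, smooth_ms)
        predicted = smooth_population_activity(
            result.member_rasters[label], tau_s, grid_s
        )
        if np.std(predicted) == 0 or np.std(actual) == 0:
            rows.append(
                {"target": label, "r_max": 0.0, "lag_at_max_s": np.nan,
                 "category": "undefined"}
            )
            continue
        r = xcorr_lagged(actual, predicted, sr, max_lag_ms)
        rows.append(
            {"target": label, "r_max": r.r_max, "lag_at_max_s": r.lag_at_max_s,
             "category": r.category}
        )
    return pd.DataFrame(rows)


def latency_report(tick_times_s, sample_rate: float) -> dict:
    """Summarise per-tick wall times from a pseudo-online run.

    The real-time flag compares the median tick cost to the sample interval;
    it is hardware-dependent and is reported, never asserted.
    """
    ticks = np.asarray(tick_times_s, dtype=float)
    if ticks.size == 0:
        raise ValueError("no tick timings logged")
    interval = 1.0 / sample_rate
    median = float(np.median(ticks))
    return {
        "n_ticks": int(ticks.size),
        "mean_s": float(np.mean(ticks)),
        "median_s": median,
        "max_s": float(np.max(ticks)),
        "sample_interval_s": interval,
        "real_time": bool(median < interval),
    }


def learning_curve(
    harness,
    trial_counts,
    seeds,
) -> pd.DataFrame:
    """Correlation as a function of training-set size.

    ``harness(k, seed) -> float`` must fit on the first ``k`` training
    trials and return the max-lag correlation on a fixed held-out set.
    Returns a tidy frame with one row per (size, seed).
    """
    trial_counts = list(trial_counts)
    rows = []
    for k in trial_counts:
        for seed in seeds:
            rows.append({"n_trials": int(k), "seed": int(seed), "r": float(harness(k, seed))})
    return pd.DataFrame(rows)


def connectivity_summary(model, include_silenced: bool = True) -> pd.DataFrame:
    """Tally SPAN-to-region wiring of a fitted decoder.

    One row per (population, region) with the member count and the summed
    absolute afferent weight; silenced members (zero readout weight) can be
    excluded.  Per population, counts sum to the number of (counted)
    members.
    """
    regions = np.asarray(model.reservoir.template.region_labels)
    rows = []
    for pop in model.populations:
        tallies: dict[str, dict] = {}
        for m, member in enumerate(pop.members):
            if not include_silenced and pop.readout_weights[m] == 0.0:
                continue
            member_regions = sorted(set(regions[member.afferents]))
            # a member wired to one anatomical cluster has one region
            for reg in member_regions:
                tally = tallies.setdefault(reg, {"n_spans": 0, "total_abs_weight": 0.0})
                tally["n_spans"] += 1
                mask = regions[member.afferents] == reg
                tally["total_abs_weight"] += float(np.abs(member.weights[mask]).sum())
        for reg in sorted(tallies):
            rows.append(
                {
                    "population": pop.label,
                    "region": reg,
                    "n_spans": tallies[reg]["n_spans"],
                    "total_abs_weight": tallies[reg]["total_abs_weight"],
                }
            )
    return pd.DataFrame(rows, columns=["population", "region", "n_spans", "total_abs_weight"])
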