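"""The Spike Pattern Association Neuron (SPAN).

A SPAN receives spike trains through weighted afferents, convolves each
spike with an alpha kernel

    alpha(t) = e * tau_s^-1 * t * exp(-t / tau_s) * Heaviside(t)

(peak value 1 at ``t = tau_s``), sums the weighted traces into a synaptic
current and fires wherever the current reaches its threshold.  Its weights
are trained with a spike-domain Widrow-Hoff (delta) rule: for every afferent
the update pulls the output train toward the desired train,

    dw_i = lambda * (e / tau^2) * [ sum_{g,f} (|t_i^f - t_d^g| + tau) exp(-|t_i^f - t_d^g| / tau)
                                  - sum_{h,f} (|t_i^f - t_out^h| + tau) exp(-|t_i^f - t_out^h| / tau) ]

so that desired spike times potentiate and actual (emitted) spike times
depress, each weighted by proximity to the afferent's own spikes.  When the
actual train equals the desired train the two sums cancel term by term and
the update is exactly zero.

All time-like quantities in these functions are unit-agnostic: pass times,
grids and time constants in one consistent unit.  Session-level code in this
package uses seconds and converts the millisecond config fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import SpikeRaster, SpikeTrain

__all__ = [
    "SPANConfig",
    "SPANNeuron",
    "alpha_kernel",
    "convolve_train",
    "span_current",
    "span_fire",
    "span_delta_update",
    "trains_match",
    "train_span",
    "van_rossum_distance",
]


@dataclass
class SPANConfig:
    """Tunable constants of a SPAN neuron (time constants in ms).

    tau_s : synaptic time constant of the alpha kernel.
    lam : learning rate of the delta rule.
    tau : time constant of the learning kernel.
    th_m : firing threshold of the neuron.
    max_epochs : training epoch budget.
    match_tolerance : spike-time tolerance (ms) for declaring the output
        train equal to the desired train.
    w_init : upper bound of the small positive uniform weight initialisation.
    """

    tau_s: float = 50.0
    lam: float = 0.05
    tau: float = 100.0
    th_m: float = 1.0
    max_epochs: int = 100
    match_tolerance: float = 20.0
    w_init: float = 0.1

    def __post_init__(self) -> None:
        if min(self.tau_s, self.lam, self.tau, self.th_m) <= 0:
            raise ValueError("tau_s, lam, tau and th_m must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class SPANNeuron:
    """One SPAN: afferent weights plus training/validation state."""

    weights: np.ndarray
    config: SPANConfig
    trained: bool = False
    accuracy: float | None = None
    afferents: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.afferents = np.asarray(self.afferents, dtype=int)


def alpha_kernel(t, tau_s: float):
    """Alpha kernel, vectorised over ``t``; zero for t < 0, peak 1 at tau_s."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.e / tau_s * t[pos] * np.exp(-t[pos] / tau_s)
    return out if out.ndim else float(out)


def convolve_train(times, tau_s: float, grid) -> np.ndarray:
    """Superpose one alpha kernel per spike onto a time grid."""
    times = np.asarray(times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if times.size == 0:
        return np.zeros_like(grid)
    lags = grid[None, :] - times[:, None]
    return alpha_kernel(lags, tau_s).sum(axis=0)


def span_current(afferent_times: list, weights, tau_s: float, grid) -> np.ndarray:
    """Weighted sum of the afferents' convolved spike trains."""
    weights = np.asarray(weights, dtype=float)
    if len(afferent_times) != weights.size:
        raise ValueError("one weight per afferent required")
    grid = np.asarray(grid, dtype=float)
    current = np.zeros_like(grid)
    for w, times in zip(weights, afferent_times):
        if w != 0.0:
            current += w * convolve_train(times, tau_s, grid)
    return current


def span_fire(current, th_m: float, grid, reset: bool = True) -> np.ndarray:
    """Threshold the current into output spike times.

    With ``reset=True`` (the default) a spike is emitted only at upward
    threshold crossings: after firing, the neuron stays silent until the
    current falls back below threshold (hysteresis), so one crossing yields
    one spike.  ``reset=False`` gives the raw comparator that spikes on every
    supra-threshold grid point.
    """
    current = np.asarray(current, dtype=float)
    grid = np.asarray(grid, dtype=float)
    above = current >= th_m
    if not reset:
        return grid[above]
    prev = np.concatenate(([False], above[:-1]))
    return grid[above & ~prev]


def span_delta_update(afferent_times: list, t_d, t_out, lam: float, tau: float) -> np.ndarray:
    """Delta-rule weight change for every afferent.

    Returns an array aligned with ``afferent_times``.  Identical desired and
    actual trains cancel exactly, giving a zero update for any input.
    """
    t_d = np.asarray(t_d, dtype=float)
    t_out = np.asarray(t_out, dtype=float)

    def kernel_sum(t_i: np.ndarray, t_ref: np.ndarray) -> float:
        if t_i.size == 0 or t_ref.size == 0:
            return 0.0
        gap = np.abs(t_i[:, None] - t_ref[None, :])
        return float(((gap + tau) * np.exp(-gap / tau)).sum())

    dw = np.empty(len(afferent_times))
    for i, times in enumerate(afferent_times):
        t_i = np.asarray(times, dtype=float)
        dw[i] = kernel_sum(t_i, t_d) - kernel_sum(t_i, t_out)
    return lam * np.e / tau**2 * dw


def trains_match(t_d, t_out, tolerance: float) -> bool:
    """True when the two spike sets pair up one-to-one within ``tolerance``.

    For points on a line the optimal one-to-one matching pairs the sorted
    sequences, so equal counts plus sorted-pairwise gaps <= tolerance is the
    exact bipartite criterion.
    """
    t_d = np.sort(np.asarray(t_d, dtype=float))
    t_out = np.sort(np.asarray(t_out, dtype=float))
    if t_d.size != t_out.size:
        return False
    if t_d.size == 0:
        return True
    return bool(np.all(np.abs(t_d - t_out) <= tolerance))


def van_rossum_distance(t_a, t_b, tau_s: float, grid) -> float:
    """L2 distance between the alpha-convolved traces of two spike trains."""
    diff = convolve_train(t_a, tau_s, grid) - convolve_train(t_b, tau_s, grid)
    dt = grid[1] - grid[0] if len(grid) > 1 else 1.0
    return float(np.sqrt(np.sum(diff**2) * dt))


def train_span(
    neuron: SPANNeuron,
    afferents: SpikeRaster | list,
    desired: SpikeTrain | np.ndarray,
    grid: np.ndarray,
    config: SPANConfig | None = None,
) -> list[float]:
    """Train a SPAN to emit the desired train given the afferent raster.

    Runs up to ``config.max_epochs`` epochs of current -> fire -> delta
    update, stopping early once the emitted train matches the desired train
    within ``match_tolerance``.  Returns the per-epoch van-Rossum-style error
    trace; non-convergence is not an error (the ``trained`` flag stays
    False).
    """
    config = config or neuron.config
    if isinstance(afferents, SpikeRaster):
        aff_times = [t.times for t in afferents.trains]
    else:
        aff_times = [np.asarray(t, dtype=float) for t in afferents]
    t_d = desired.times if isinstance(desired, SpikeTrain) else np.asarray(desired, dtype=float)
    grid = np.asarray(grid, dtype=float)

    # the afferent convolution matrix is fixed across epochs
    conv = np.stack([convolve_train(t, config.tau_s, grid) for t in aff_times]) if aff_times else None

    trace: list[float] = []
    neuron.trained = False
    for _ in range(config.max_epochs):
        current = neuron.weights @ conv if conv is not None else np.zeros_like(grid)
        t_out = span_fire(current, config.th_m, grid)
        trace.append(van_rossum_distance(t_d, t_out, config.tau_s, grid))
        if trains_match(t_d, t_out, config.match_tolerance):
            neuron.trained = True
            break
        if conv is None:
            break  # nothing to update
        neuron.weights = neuron.weights + span_delta_update(
            aff_times, t_d, t_out, config.lam, config.tau
        )
    return trace
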