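"""3D spiking reservoir: brain-template placement, small-world wiring,
leaky integrate-and-fire dynamics and fire-triggered STDP.

The reservoir places LIF neurons on a regular grid inside an ellipsoidal
volume, each neuron labelled with a simplified anatomical region
(octant-by-depth); a user-supplied coordinate table with custom region
labels can stand in for the packaged template when atlas-faithful runs are
wanted.  Input channels are mapped onto their nearest neurons, synapses are
drawn with a distance-decaying probability (small-world principle), and an
unsupervised pass shapes the weights with a *fire-triggered* STDP rule:
weights change only when a neuron emits a spike, and a fire event updates
both the incoming synapses (against each presynaptic neuron's last spike)
and the outgoing ones (against each postsynaptic neuron's last spike).
Receiving a spike never updates a synapse.

The classic all-pairs STDP sum

    dw = sum_f sum_n W(t_post^n - t_pre^f),
    W(x) = A+ exp(-x/tau+)  for x > 0,   -A- exp(x/tau-)  for x < 0

is exposed separately (:func:`stdp_total_update`) for offline analysis; the
online rule applies the same window W to nearest (most recent) spikes only.
W(0) is defined as 0: simultaneous spikes carry no causal information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import SpikeRaster, SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "BrainTemplate",
    "LIFParams",
    "STDPParams",
    "Reservoir",
    "build_template",
    "default_montage",
    "map_inputs",
    "init_small_world",
    "stdp_window",
    "stdp_total_update",
    "ReservoirSim",
    "run_unsupervised",
    "extract_clusters",
]

# millimetre semi-axes of the default head ellipsoid (x right, y anterior,
# z superior) and the default grid spacing
DEFAULT_SEMI_AXES = (60.0, 80.0, 50.0)
DEFAULT_RESOLUTION = 15.0

# 32-channel 10-20-style montage as (azimuth deg from nasion, positive to the
# right; inclination deg from the vertex); projected onto the head ellipsoid.
_MONTAGE_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (-18, 72), "Fp2": (18, 72),
    "F7": (-54, 72), "F3": (-40, 50), "Fz": (0, 36), "F4": (40, 50), "F8": (54, 72),
    "FC5": (-70, 55), "FC1": (-25, 25), "FC2": (25, 25), "FC6": (70, 55),
    "T7": (-90, 72), "C3": (-90, 36), "Cz": (0, 0), "C4": (90, 36), "T8": (90, 72),
    "TP9": (-108, 85), "CP5": (-110, 55), "CP1": (-155, 25), "CP2": (155, 25),
    "CP6": (110, 55), "TP10": (108, 85),
    "P7": (-126, 72), "P3": (-140, 50), "Pz": (180, 36), "P4": (140, 50), "P8": (126, 72),
    "PO9": (-152, 85), "O1": (-162, 72), "Oz": (180, 72), "O2": (162, 72), "PO10": (152, 85),
}


@dataclass
class BrainTemplate:
    """Neuron coordinates (mm) plus one region label per neuron."""

    coords: np.ndarray
    region_labels: list[str]
    resolution: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a template needs at least 2 neurons")
        if len(self.region_labels) != self.coords.shape[0]:
            raise ValueError("one region label per neuron required")
        uniq = {tuple(row) for row in np.round(self.coords, 9)}
        if len(uniq) != self.coords.shape[0]:
            raise ValueError("duplicate neuron coordinates")

    @property
    def n_neurons(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        df.insert(0, "label", [f"n{i}" for i in range(self.n_neurons)])
        df["region"] = self.region_labels
        return df

    @classmethod
    def from_csv(cls, path, resolution: float = DEFAULT_RESOLUTION) -> "BrainTemplate":
        df = pd.read_csv(path)
        regions = df["region"].astype(str).tolist() if "region" in df.columns else ["all"] * len(df)
        return cls(df[["x", "y", "z"]].to_numpy(dtype=float), regions, resolution)


@dataclass
class LIFParams:
    """Leaky integrate-and-fire constants.

    Exponential membrane leak with time constant ``tau_m`` (ms), firing
    threshold in weight units, reset to 0 after a spike, absolute refractory
    period in ms (default one 100 Hz tick).
    """

    threshold: float = 0.5
    tau_m: float = 15.0
    refractory: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.tau_m <= 0 or self.refractory < 0:
            raise ValueError("invalid LIF parameters")


@dataclass
class STDPParams:
    """STDP window constants; amplitudes dimensionless, taus in ms."""

    a_plus: float = 0.01
    a_minus: float = 0.01
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    enabled: bool = True
    w_min: float = -1.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ValueError("STDP amplitudes and time constants must be positive")


@dataclass
class Reservoir:
    """Template + synapses + input mapping + LIF constants."""

    template: BrainTemplate
    weights: np.ndarray           # dense (n, n), pre -> post; 0 where no synapse
    adjacency: np.ndarray         # bool (n, n) synapse-existence mask
    input_map: dict[str, int] = field(default_factory=dict)
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        n = self.template.n_neurons
        self.weights = np.asarray(self.weights, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.weights.shape != (n, n) or self.adjacency.shape != (n, n):
            raise ValueError("weights/adjacency must be (n, n)")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-synapses are not allowed")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        vals = list(self.input_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError("input_map must be injective")

    @property
    def n_neurons(self) -> int:
        return self.template.n_neurons

    @property
    def n_synapses(self) -> int:
        return int(self.adjacency.sum())

    def weights_frame(self) -> pd.DataFrame:
        pre, post = np.nonzero(self.adjacency)
        return pd.DataFrame({"pre": pre, "post": post, "w": self.weights[pre, post]})


def build_template(
    resolution: float = DEFAULT_RESOLUTION,
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
    depth_split: float = 0.6,
) -> BrainTemplate:
    """Regular grid of neurons inside an ellipsoid, labelled octant-by-depth.

    Regions are named like ``RAS-sup``: hemisphere (L/R), anterior/posterior,
    superior/inferior, and a depth shell (``deep`` when the normalised radius
    is below ``depth_split``, else ``sup``).  The construction is fully
    deterministic given its arguments.
    """
    a, b, c = semi_axes
    ax = np.arange(-a, a + 1e-9, resolution)
    ay = np.arange(-b, b + 1e-9, resolution)
    az = np.arange(-c, c + 1e-9, resolution)
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rho = np.sqrt((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2)
    inside = rho <= 1.0
    pts, rho = pts[inside], rho[inside]
    if pts.shape[0] < 2:
        raise ValueError("resolution too coarse: fewer than 2 neurons")
    labels = []
    for (x, y, z), r in zip(pts, rho):
        oct_label = ("R" if x >= 0 else "L") + ("A" if y >= 0 else "P") + ("S" if z >= 0 else "I")
        labels.append(f"{oct_label}-{'deep' if r < depth_split else 'sup'}")
    return BrainTemplate(pts, labels, resolution)


def default_montage(
    channels: list[str] | None = None,
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
) -> pd.DataFrame:
    """Packaged 32-channel 10-20-style montage projected on the head ellipsoid."""
    channels = channels or list(_MONTAGE_ANGLES)
    a, b, c = semi_axes
    rows = []
    for ch in channels:
        az, incl = _MONTAGE_ANGLES[ch]
        az_r, incl_r = np.deg2rad(az), np.deg2rad(incl)
        unit = np.array(
            [np.sin(incl_r) * np.sin(az_r), np.sin(incl_r) * np.cos(az_r), np.cos(incl_r)]
        )
        rows.append({"label": ch, "x": a * unit[0], "y": b * unit[1], "z": c * unit[2]})
    return pd.DataFrame(rows)


def map_inputs(
    template: BrainTemplate,
    montage: pd.DataFrame,
    warn_distance: float | None = None,
) -> dict[str, int]:
    """Map each channel to its nearest template neuron (Euclidean distance).

    Channels are processed in lexicographic label order; when two channels
    compete for one neuron the later channel falls through to its nearest
    *free* neuron, so the mapping is injective and deterministic.
    """
    if len(montage) > template.n_neurons:
        raise ValueError("more channels than template neurons")
    warn_distance = warn_distance if warn_distance is not None else 3.0 * template.resolution
    taken: set[int] = set()
    input_map: dict[str, int] = {}
    order = montage.sort_values("label")
    for _, row in order.iterrows():
        p = np.array([row["x"], row["y"], row["z"]], dtype=float)
        dist = np.linalg.norm(template.coords - p, axis=1)
        for idx in np.argsort(dist, kind="stable"):
            if int(idx) not in taken:
                if dist[idx] > warn_distance:
                    logger.warning(
                        "channel %s mapped %.1f mm away from its montage position",
                        row["label"], dist[idx],
                    )
                taken.add(int(idx))
                input_map[str(row["label"])] = int(idx)
                break
    return input_map


def init_small_world(
    template: BrainTemplate,
    seed: int,
    radius_fraction: float = 0.25,
    inhibitory_fraction: float = 0.25,
    w_scale: float = 8.0,
    p0: float = 0.8,
    lambda_d: float | None = None,
    inhibitory_gain: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small-world synapse set: distance-decaying connection probability.

    Every ordered pair within radius ``r = radius_fraction * max pairwise
    distance`` is connected with probability ``p0 * exp(-d / lambda_d)``
    (``lambda_d`` defaults to ``r``); the weight magnitude is drawn as
    ``Uniform(0, w_scale) / d``.  A seeded fraction of presynaptic neurons is
    inhibitory: all their outgoing weights are negated and scaled by
    ``inhibitory_gain`` (inhibition-dominated wiring stabilises the recurrent
    dynamics so reservoir activity stays stimulus-driven).  Returns
    ``(weights, adjacency)``.
    """
    if not 0 < radius_fraction <= 1:
        raise ValueError("radius_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    coords = template.coords
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    r = radius_fraction * d.max()
    lam = lambda_d if lambda_d is not None else r
    candidate = (d <= r) & (d > 0)
    p = np.where(candidate, p0 * np.exp(-d / np.maximum(lam, 1e-12)), 0.0)
    adjacency = rng.random((n, n)) < p
    np.fill_diagonal(adjacency, False)
    mag = rng.uniform(0.0, w_scale, size=(n, n)) / np.maximum(d, 1e-12)
    weights = np.where(adjacency, mag, 0.0)
    inhibitory = rng.random(n) < inhibitory_fraction
    weights[inhibitory, :] *= -inhibitory_gain
    return weights, adjacency


def stdp_window(x, params: STDPParams):
    """STDP learning window W(x); x in ms, W(0) = 0 by convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    neg = x < 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = params.a_plus * np.exp(-x[pos] / params.tau_plus)
        out[neg] = -params.a_minus * np.exp(x[neg] / params.tau_minus)
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return out if out.ndim else float(out)


def stdp_total_update(pre_train: SpikeTrain | np.ndarray, post_train, params: STDPParams) -> float:
    """All-pairs STDP sum over every (pre, post) spike pair."""
    pre = pre_train.times if isinstance(pre_train, SpikeTrain) else np.asarray(pre_train, float)
    post = post_train.times if isinstance(post_train, SpikeTrain) else np.asarray(post_train, float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    gaps = post[None, :] - pre[:, None]
    return float(stdp_window(gaps, params).sum())


class ReservoirSim:
    """Tick-by-tick LIF simulation of a reservoir, with optional online STDP.

    One synaptic delay of a single tick: spikes emitted at tick ``k`` are
    delivered to their postsynaptic targets at tick ``k + 1``.  Input-mapped
    neurons relay encoder spikes 1:1 (an input spike forces a reservoir
    spike at that neuron on the same tick), so input drive is not attenuated
    by the leak.  Online STDP fires only at spike-emission events, touching
    both the incoming and the outgoing synapses of the firing neuron against
    the counterpart's most recent spike.
    """

    def __init__(self, reservoir: Reservoir, dt: float, stdp: STDPParams | None = None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.res = reservoir
        self.dt = dt
        self.dt_ms = dt * 1000.0
        self.stdp = stdp
        n = reservoir.n_neurons
        self.v = np.zeros(n)
        self.refr_until = np.full(n, -np.inf)
        self.last_spike_ms = np.full(n, -np.inf)
        self.decay = np.exp(-self.dt_ms / reservoir.lif.tau_m)
        self._prev_fired = np.array([], dtype=int)
        self.spike_times: list[list[float]] = [[] for _ in range(n)]
        self.tick = 0

    @property
    def t(self) -> float:
        return self.tick * self.dt

    def step(self, input_fired: np.ndarray) -> np.ndarray:
        """Advance one tick; ``input_fired`` are neuron indices forced to fire."""
        res, t = self.res, self.t
        t_ms = t * 1000.0
        self.v *= self.decay
        if self._prev_fired.size:
            self.v += res.weights[self._prev_fired, :].sum(axis=0)
        ready = t_ms >= self.refr_until
        fired_mask = (self.v >= res.lif.threshold) & ready
        if input_fired.size:
            fired_mask[input_fired] = True  # deterministic 1:1 relay
        fired = np.flatnonzero(fired_mask)
        if fired.size:
            last_before = self.last_spike_ms.copy()
            self.v[fired] = 0.0
            self.refr_until[fired] = t_ms + res.lif.refractory
            self.last_spike_ms[fired] = t_ms
            for j in fired:
                self.spike_times[j].append(t)
            if self.stdp is not None and self.stdp.enabled:
                self._apply_stdp(fired, t_ms, last_before)
        self._prev_fired = fired
        self.tick += 1
        return fired

    def _apply_stdp(self, fired: np.ndarray, t_ms: float, last_before: np.ndarray) -> None:
        p = self.stdp
        W, adj = self.res.weights, self.res.adjacency
        # incoming synapses i -> j for each firing j: gap = t_fire - last(i)
        gap_in = t_ms - last_before
        delta_in = stdp_window(gap_in, p)
        W[:, fired] += delta_in[:, None] * adj[:, fired]
        # outgoing synapses j -> k: gap = last(k) - t_fire
        gap_out = last_before - t_ms
        delta_out = stdp_window(gap_out, p)
        W[fired, :] += delta_out[None, :] * adj[fired, :]
        W[:, fired] = np.clip(W[:, fired], p.w_min, p.w_max)
        W[fired, :] = np.clip(W[fired, :], p.w_min, p.w_max)

    def raster(self, duration: float | None = None) -> SpikeRaster:
        if duration is None:
            duration = max(self.tick - 1, 0) * self.dt
        trains = [
            SpikeTrain(np.asarray(ts, dtype=float), duration) for ts in self.spike_times
        ]
        return SpikeRaster(trains, [f"n{i}" for i in range(len(trains))])


def _raster_to_ticks(raster: SpikeRaster, input_map: dict[str, int], sample_rate: float):
    """Per-tick lists of forced-fire neuron indices for the encoder raster."""
    missing = [l for l in raster.labels if l not in input_map]
    if missing:
        raise KeyError(f"raster channels absent from input_map: {missing}")
    n_ticks = int(round(raster.duration * sample_rate)) + 1
    ticks: list[list[int]] = [[] for _ in range(n_ticks)]
    for label, train in zip(raster.labels, raster.trains):
        neuron = input_map[label]
        for t in train.times:
            ticks[int(round(t * sample_rate))].append(neuron)
    return [np.array(sorted(set(k)), dtype=int) for k in ticks]


def run_unsupervised(
    reservoir: Reservoir,
    raster: SpikeRaster,
    sample_rate: float,
    stdp: STDPParams | None = None,
) -> SpikeRaster:
    """Drive the reservoir with an encoder raster, learning via online STDP.

    Mutates ``reservoir.weights`` in place (unless learning is disabled) and
    returns the full reservoir spike raster for the supervised stage.
    """
    stdp = stdp if stdp is not None else STDPParams()
    sim = ReservoirSim(reservoir, 1.0 / sample_rate, stdp)
    for input_fired in _raster_to_ticks(raster, reservoir.input_map, sample_rate):
        sim.step(input_fired)
    return sim.raster(raster.duration)


def extract_clusters(reservoir: Reservoir | BrainTemplate) -> dict[str, np.ndarray]:
    """Partition neurons by region label; keys sorted, no empty cluster."""
    template = reservoir.template if isinstance(reservoir, Reservoir) else reservoir
    labels = np.asarray(template.region_labels)
    return {
        lab: np.flatnonzero(labels == lab) for lab in sorted(set(template.region_labels))
    }
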