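"""Evolving SPAN-population output layer and the end-to-end decoder.

One SPAN population per target signal.  When a training trial arrives whose
desired spike train no existing member of the population can reproduce, a
new SPAN is spawned, wired to all neurons of one anatomical cluster
(clusters taken round-robin per population so populations progressively
cover brain regions), trained with the delta rule, and appended.  After the
supervised pass each member is validated across the training trials; a
member whose accuracy falls below ``kappa`` times the population's best is
silenced (readout weight zero) but retained.

Each population feeds one integrate-and-fire readout neuron: its average
synaptic current is the member-weighted mean of the members' alpha-convolved
output trains, and its binary state is 1 whenever that current reaches the
readout threshold.  The readout state sequence is the population's predicted
spike train, decoded back to an analog signal with the target's stored
encoding threshold and initial value.

Prediction is strictly causal and tick-by-tick (pseudo-online): encoding,
reservoir dynamics (plasticity frozen), member traces, firing and readout
all advance one sample at a time, so streaming and batch prediction are the
same computation.

Internally the supervised stage works in milliseconds (matching the SPAN
config fields); raster interfaces use seconds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import spike_codec
from .reservoir import (
    BrainTemplate,
    LIFParams,
    Reservoir,
    ReservoirSim,
    STDPParams,
    build_template,
    extract_clusters,
    init_small_world,
    map_inputs,
    run_unsupervised,
)
from .signals import ContinuousSignal, SpikeRaster, SpikeTrain
from .span_core import (
    SPANConfig,
    SPANNeuron,
    convolve_train,
    span_fire,
    train_span,
    trains_match,
)

__all__ = [
    "DecoderConfig",
    "SPANPopulation",
    "DecoderModel",
    "PredictionResult",
    "readout_current",
    "readout_state",
    "spawn_span",
    "validate_population",
    "fit",
    "extend",
    "predict_stream",
    "predict_labels",
]

NO_EVENT = "no_event"


@dataclass
class DecoderConfig:
    """All tunables of the decoder in one serialisable bundle."""

    encoding_factor_in: float = 0.5
    encoding_factor_target: float = 2.5
    template_resolution: float = 15.0
    semi_axes: tuple[float, float, float] = (60.0, 80.0, 50.0)
    radius_fraction: float = 0.25
    inhibitory_fraction: float = 0.25
    w_scale: float = 8.0
    p0: float = 0.8
    inhibitory_gain: float = 4.0
    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    span: SPANConfig = field(default_factory=lambda: SPANConfig(max_epochs=50))
    activity_tau: float = 300.0  # ms; readout / population-activity kernel
    th_n: float = 0.5          # readout threshold, normalised-current units
    kappa: float = 0.8         # validation retention factor
    continual_stdp: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["semi_axes"] = list(self.semi_axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderConfig":
        d = dict(d)
        d["semi_axes"] = tuple(d.get("semi_axes", (60.0, 80.0, 50.0)))
        d["lif"] = LIFParams(**d.get("lif", {}))
        d["stdp"] = STDPParams(**d.get("stdp", {}))
        d["span"] = SPANConfig(**d.get("span", {}))
        return cls(**d)


@dataclass
class SPANPopulation:
    """Per-target population vector of SPANs plus its readout neuron."""

    label: str
    members: list[SPANNeuron] = field(default_factory=list)
    readout_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    th_n: float = 0.5
    cluster_cursor: int = 0
    decode_sign: int = 1

    def __post_init__(self) -> None:
        if self.th_n <= 0:
            raise ValueError("readout threshold must be positive")
        self.readout_weights = np.asarray(self.readout_weights, dtype=float)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _member_output_ms(member: SPANNeuron, aff_times_ms: list, grid_ms: np.ndarray,
                      span: SPANConfig) -> np.ndarray:
    """A member's output spike times (ms) on one trial, batch evaluated."""
    current = np.zeros_like(grid_ms)
    for w, times in zip(member.weights, aff_times_ms):
        if w != 0.0:
            current += w * convolve_train(times, span.tau_s, grid_ms)
    return span_fire(current, span.th_m, grid_ms)


def readout_current(population: SPANPopulation, member_out_ms: list, grid_ms: np.ndarray,
                    tau_s: float) -> np.ndarray:
    """Average synaptic current of the readout neuron over a grid.

    ``member_out_ms`` holds each member's output spike times.  The current
    is the readout-weighted mean of the members' alpha-convolved trains.
    """
    if population.n_members == 0:
        raise ValueError("undefined current: population has no members")
    acc = np.zeros_like(np.asarray(grid_ms, dtype=float))
    for w, times in zip(population.readout_weights, member_out_ms):
        if w != 0.0:
            acc += w * convolve_train(times, tau_s, grid_ms)
    return acc / population.n_members


def readout_state(population: SPANPopulation, current) -> np.ndarray:
    """Binary readout state: 1 wherever the current reaches the threshold."""
    return (np.asarray(current, dtype=float) >= population.th_n).astype(int)


def spawn_span(
    population: SPANPopulation,
    aff_all_ms: list,
    desired_ms: np.ndarray,
    clusters: dict[str, np.ndarray],
    span: SPANConfig,
    grid_ms: np.ndarray,
    rng: np.random.Generator,
    cluster_order: list[str] | None = None,
) -> SPANNeuron | None:
    """Spawn-and-train guard for one training trial.

    If a trained member already reproduces the desired train (within the
    match tolerance) nothing is spawned.  Otherwise a new SPAN wired to the
    next cluster in round-robin order is trained on this trial and appended
    regardless of convergence.  ``cluster_order`` fixes the round-robin
    sequence (default: sorted labels).  Returns the new member or None.
    """
    for member in population.members:
        if not member.trained:
            continue
        out = _member_output_ms(
            member, [aff_all_ms[i] for i in member.afferents], grid_ms, span
        )
        if trains_match(desired_ms, out, span.match_tolerance):
            return None
    keys = cluster_order if cluster_order is not None else sorted(clusters)
    cluster = clusters[keys[population.cluster_cursor % len(keys)]]
    population.cluster_cursor += 1
    member = SPANNeuron(
        weights=rng.uniform(0.0, span.w_init, size=cluster.size),
        config=span,
        afferents=cluster.copy(),
    )
    train_span(member, [aff_all_ms[i] for i in cluster], desired_ms, grid_ms, span)
    population.members.append(member)
    population.readout_weights = np.append(population.readout_weights, 1.0)
    return member


def validate_population(
    population: SPANPopulation,
    trials_aff_ms: list[list],
    trials_desired_ms: list[np.ndarray],
    grids_ms: list[np.ndarray],
    span: SPANConfig,
    kappa: float,
) -> None:
    """Score members over validation trials and silence the weak ones.

    A member's accuracy is the fraction of trials whose output matches the
    desired train.  Members within ``kappa`` of the population's best keep
    readout weight equal to their accuracy; the rest get weight 0 but stay
    in the population.
    """
    if not trials_aff_ms:
        raise ValueError("validation needs at least one trial")
    if population.n_members == 0:
        return
    acc = np.zeros(population.n_members)
    for m, member in enumerate(population.members):
        hits = 0
        for aff_all, desired, grid in zip(trials_aff_ms, trials_desired_ms, grids_ms):
            out = _member_output_ms(
                member, [aff_all[i] for i in member.afferents], grid, span
            )
            hits += trains_match(desired, out, span.match_tolerance)
        acc[m] = hits / len(trials_aff_ms)
        member.accuracy = float(acc[m])
    best = acc.max()
    keep = acc >= kappa * best
    population.readout_weights = np.where(keep, acc, 0.0)


@dataclass
class PredictionResult:
    """Output of a pseudo-online prediction run."""

    member_rasters: dict[str, SpikeRaster]
    readout_trains: dict[str, SpikeTrain]
    readout_states: np.ndarray            # (n_ticks, n_populations)
    population_labels: list[str]
    decoded: ContinuousSignal
    reservoir_raster: SpikeRaster
    tick_wall_times: np.ndarray
    sample_rate: float

    def states_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.readout_states, columns=self.population_labels)
        df.insert(0, "time", np.arange(len(df)) / self.sample_rate)
        return df


class DecoderModel:
    """A fitted decoder: reservoir + clusters + SPAN populations + codecs."""

    def __init__(
        self,
        config: DecoderConfig,
        seed: int,
        reservoir: Reservoir,
        montage: pd.DataFrame,
        thresholds_in: spike_codec.EncodingThresholds,
        thresholds_target: spike_codec.EncodingThresholds,
        populations: list[SPANPopulation],
    ):
        self.config = config
        self.seed = seed
        self.reservoir = reservoir
        self.montage = montage.reset_index(drop=True)
        self.thresholds_in = thresholds_in
        self.thresholds_target = thresholds_target
        self.populations = populations
        self.clusters = extract_clusters(reservoir)
        self.cluster_order: list[str] | None = None
        self._train_raster: SpikeRaster | None = None  # transient caches
        self._rng: np.random.Generator | None = None

    @property
    def target_labels(self) -> list[str]:
        return [p.label for p in self.populations]

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        wf = self.reservoir.weights_frame()
        return {
            "format": "bisnn-decoder-v1",
            "config": self.config.to_dict(),
            "seed": int(self.seed),
            "montage": self.montage.to_dict(orient="list"),
            "template": {
                "coords": self.reservoir.template.coords.tolist(),
                "region_labels": list(self.reservoir.template.region_labels),
                "resolution": self.reservoir.template.resolution,
            },
            "input_map": {k: int(v) for k, v in self.reservoir.input_map.items()},
            "synapses": {
                "pre": wf["pre"].tolist(),
                "post": wf["post"].tolist(),
                "w": wf["w"].tolist(),
            },
            "thresholds_in": self.thresholds_in.to_dict(),
            "thresholds_target": self.thresholds_target.to_dict(),
            "cluster_order": self.cluster_order,
            "populations": [
                {
                    "label": p.label,
                    "th_n": p.th_n,
                    "cluster_cursor": int(p.cluster_cursor),
                    "decode_sign": int(p.decode_sign),
                    "readout_weights": p.readout_weights.tolist(),
                    "members": [
                        {
                            "weights": m.weights.tolist(),
                            "afferents": m.afferents.tolist(),
                            "trained": bool(m.trained),
                            "accuracy": m.accuracy,
                        }
                        for m in p.members
                    ],
                }
                for p in self.populations
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderModel":
        config = DecoderConfig.from_dict(d["config"])
        template = BrainTemplate(
            np.array(d["template"]["coords"]),
            list(d["template"]["region_labels"]),
            d["template"]["resolution"],
        )
        n = template.n_neurons
        weights = np.zeros((n, n))
        adjacency = np.zeros((n, n), dtype=bool)
        pre = np.array(d["synapses"]["pre"], dtype=int)
        post = np.array(d["synapses"]["post"], dtype=int)
        weights[pre, post] = np.array(d["synapses"]["w"], dtype=float)
        adjacency[pre, post] = True
        reservoir = Reservoir(template, weights, adjacency, dict(d["input_map"]), config.lif)
        populations = []
        for pd_ in d["populations"]:
            members = [
                SPANNeuron(
                    weights=np.array(m["weights"], dtype=float),
                    config=config.span,
                    trained=m["trained"],
                    accuracy=m["accuracy"],
                    afferents=np.array(m["afferents"], dtype=int),
                )
                for m in pd_["members"]
            ]
            populations.append(
                SPANPopulation(
                    label=pd_["label"],
                    members=members,
                    readout_weights=np.array(pd_["readout_weights"], dtype=float),
                    th_n=pd_["th_n"],
                    cluster_cursor=pd_["cluster_cursor"],
                    decode_sign=pd_["decode_sign"],
                )
            )
        model = cls(
            config,
            d["seed"],
            reservoir,
            pd.DataFrame(d["montage"]),
            spike_codec.EncodingThresholds.from_dict(d["thresholds_in"]),
            spike_codec.EncodingThresholds.from_dict(d["thresholds_target"]),
            populations,
        )
        model.cluster_order = d.get("cluster_order")
        return model

    @classmethod
    def from_json(cls, path) -> "DecoderModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------- fit


def _trial_tick_bounds(trials, sample_rate: float) -> list[tuple[int, int]]:
    return [
        (int(round(s * sample_rate)), int(round(e * sample_rate))) for s, e in trials
    ]


def _window_times_ms(times_s: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    m = (times_s >= t_lo) & (times_s < t_hi)
    return (times_s[m] - t_lo) * 1000.0


def _supervised_pass(
    model: DecoderModel,
    res_raster: SpikeRaster,
    target_rasters: SpikeRaster,
    trials,
    sample_rate: float,
    rng: np.random.Generator,
) -> None:
    """Spawn/train members trial by trial, then re-validate on those trials."""
    span = model.config.span
    dt_ms = 1000.0 / sample_rate
    res_times = [t.times for t in res_raster.trains]

    if model.cluster_order is None:
        # round-robin visits the regions with the most reservoir spiking
        # first, so populations wire to informative areas before silent ones
        counts = {
            lab: sum(res_raster.trains[i].n for i in idx)
            for lab, idx in model.clusters.items()
        }
        model.cluster_order = sorted(model.clusters, key=lambda l: (-counts[l], l))

    trial_aff, trial_des, trial_grids = [], [], []
    for (t_lo, t_hi) in trials:
        n_ticks = int(round((t_hi - t_lo) * sample_rate))
        grid_ms = np.arange(n_ticks) * dt_ms
        aff_all = [_window_times_ms(times, t_lo, t_hi) for times in res_times]
        trial_aff.append(aff_all)
        trial_grids.append(grid_ms)
        trial_des.append(
            {
                label: _window_times_ms(target_rasters.train(label).times, t_lo, t_hi)
                for label in target_rasters.labels
            }
        )

    for aff_all, grid_ms, desired_by_label in zip(trial_aff, trial_grids, trial_des):
        for pop in model.populations:
            spawn_span(
                pop, aff_all, desired_by_label[pop.label], model.clusters, span,
                grid_ms, rng, cluster_order=model.cluster_order,
            )
    if trial_aff:
        for pop in model.populations:
            validate_population(
                pop,
                trial_aff,
                [d[pop.label] for d in trial_des],
                trial_grids,
                span,
                model.config.kappa,
            )


def fit(
    inputs: ContinuousSignal,
    targets: ContinuousSignal,
    montage: pd.DataFrame,
    trials,
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> DecoderModel:
    """Fit a decoder on one training session.

    Pipeline: encode inputs and targets -> build and wire the reservoir ->
    one unsupervised STDP pass over the whole session -> extract anatomical
    clusters -> per trial and per target, spawn/train SPANs on the trial's
    reservoir raster against the target's desired spike train -> validate
    members across the training trials.

    ``trials`` is a list of (start, end) times in seconds.  An empty list
    yields a model with empty populations.
    """
    if inputs.sample_rate != targets.sample_rate or inputs.n_samples != targets.n_samples:
        raise ValueError("inputs and targets must share sample rate and length")
    config = config or DecoderConfig()
    rng = np.random.default_rng(seed)
    init_seed = int(rng.integers(2**31))

    thresholds_in = spike_codec.compute_thresholds(inputs, config.encoding_factor_in)
    in_raster = spike_codec.encode(inputs, thresholds_in).unsigned()

    template = build_template(config.template_resolution, config.semi_axes)
    input_map = map_inputs(template, montage)
    weights, adjacency = init_small_world(
        template,
        init_seed,
        radius_fraction=config.radius_fraction,
        inhibitory_fraction=config.inhibitory_fraction,
        w_scale=config.w_scale,
        p0=config.p0,
        inhibitory_gain=config.inhibitory_gain,
    )
    reservoir = Reservoir(template, weights, adjacency, input_map, config.lif)
    run_unsupervised(reservoir, in_raster, inputs.sample_rate, config.stdp)
    # supervised learning consumes the *frozen* reservoir's response, the same
    # dynamics prediction will run, not the raster emitted while STDP was
    # still reshaping the weights
    res_raster = run_unsupervised(
        reservoir, in_raster, inputs.sample_rate, replace(config.stdp, enabled=False)
    )

    thresholds_target = spike_codec.compute_thresholds(targets, config.encoding_factor_target)
    target_rasters = spike_codec.encode(targets, thresholds_target)
    populations = []
    for label in targets.channel_labels:
        signed = target_rasters.train(label)
        majority = 1 if (signed.n == 0 or signed.signs.sum() >= 0) else -1
        populations.append(
            SPANPopulation(label=label, th_n=config.th_n, decode_sign=majority)
        )

    model = DecoderModel(
        config, seed, reservoir, montage, thresholds_in, thresholds_target, populations
    )
    model._train_raster = res_raster
    model._rng = rng
    _supervised_pass(
        model, res_raster, target_rasters.unsigned(), list(trials), inputs.sample_rate, rng
    )
    return model


def extend(
    model: DecoderModel,
    targets: ContinuousSignal,
    trials,
    seed: int | None = None,
) -> DecoderModel:
    """Continue incremental learning on further trials of the same session.

    The reservoir stays frozen after its single unsupervised pass; the
    cached training-session raster is segmented at the new trial boundaries
    and the spawn/validate cycle continues where it left off.  With the
    default ``seed=None`` the random stream of the original fit continues,
    so fitting trials 1..k and then extending with k+1..K spawns exactly the
    members a single pass over 1..K would have.  Member accuracies are
    re-validated on the trials given here.
    """
    if model._train_raster is None:
        raise ValueError("extend requires the in-memory model that fit returned")
    rng = model._rng if seed is None else np.random.default_rng(seed)
    target_rasters = spike_codec.encode(targets, model.thresholds_target).unsigned()
    _supervised_pass(
        model, model._train_raster, target_rasters, list(trials), targets.sample_rate, rng
    )
    return model


# ----------------------------------------------------------------- predict


class _AlphaTrace:
    """O(1)-per-tick alpha-kernel convolution of streaming spike trains.

    Maintains S0 = sum_f exp(-(t - t_f)/tau) and S1 = sum_f (t - t_f)
    exp(-(t - t_f)/tau); the convolved trace is (e / tau) * S1.  A spike
    registered at the current tick contributes zero (alpha(0) = 0) and grows
    in on subsequent ticks, exactly as the batch convolution does.
    """

    def __init__(self, n: int, tau_ms: float, dt_ms: float):
        self.tau = tau_ms
        self.dt = dt_ms
        self.decay = np.exp(-dt_ms / tau_ms)
        self.s0 = np.zeros(n)
        self.s1 = np.zeros(n)

    def advance(self) -> None:
        self.s1 = self.decay * (self.s1 + self.dt * self.s0)
        self.s0 = self.decay * self.s0

    def add_spikes(self, idx) -> None:
        self.s0[idx] += 1.0

    @property
    def value(self) -> np.ndarray:
        return np.e / self.tau * self.s1


def predict_stream(
    model: DecoderModel,
    inputs: ContinuousSignal,
    mode: str = "streaming",
) -> PredictionResult:
    """Pseudo-online prediction over an input session.

    ``mode`` is "streaming" or "batch"; both run the identical tick-by-tick
    computation (prediction is causal by construction), so their outputs are
    bit-for-bit equal — "batch" merely skips the per-tick wall-time log.
    """
    if mode not in ("streaming", "batch"):
        raise ValueError("mode must be 'streaming' or 'batch'")
    missing = [c for c in inputs.channel_labels if c not in model.reservoir.input_map]
    if missing:
        raise ValueError(f"input channels unknown to the model: {missing}")
    span = model.config.span
    sr = inputs.sample_rate
    dt_ms = 1000.0 / sr
    n_ticks = inputs.n_samples
    n_neurons = model.reservoir.n_neurons
    pops = model.populations

    stdp = model.config.stdp if model.config.continual_stdp else None
    sim = ReservoirSim(model.reservoir, 1.0 / sr, stdp)

    ch_idx = np.array(
        [model.reservoir.input_map[c] for c in inputs.channel_labels], dtype=int
    )
    ch_th = np.array([model.thresholds_in[c].th for c in inputs.channel_labels])

    res_trace = _AlphaTrace(n_neurons, span.tau_s, dt_ms)
    member_traces = [
        _AlphaTrace(p.n_members, model.config.activity_tau, dt_ms) for p in pops
    ]
    member_above = [np.zeros(p.n_members, dtype=bool) for p in pops]
    member_spikes: list[list[list[float]]] = [
        [[] for _ in range(p.n_members)] for p in pops
    ]
    states = np.zeros((n_ticks, len(pops)), dtype=int)
    wall = np.empty(n_ticks) if mode == "streaming" else np.zeros(0)

    prev_sample = inputs.values[0]
    for k in range(n_ticks):
        tic = time.perf_counter() if mode == "streaming" else 0.0
        # causal threshold encoding of the new sample
        if k == 0:
            input_fired = np.array([], dtype=int)
        else:
            sample = inputs.values[k]
            diff = np.abs(sample - prev_sample)
            crossing = (diff >= ch_th) & (ch_th > 0)
            input_fired = np.unique(ch_idx[crossing])
            prev_sample = sample
        fired = sim.step(input_fired)

        res_trace.advance()
        res_trace.add_spikes(fired)
        s_res = res_trace.value

        for p_i, pop in enumerate(pops):
            trace = member_traces[p_i]
            trace.advance()
            if pop.n_members:
                currents = np.array(
                    [m.weights @ s_res[m.afferents] for m in pop.members]
                )
                above = currents >= span.th_m
                new_spikes = above & ~member_above[p_i]
                member_above[p_i] = above
                fired_members = np.flatnonzero(new_spikes)
                if fired_members.size:
                    trace.add_spikes(fired_members)
                    t_now = k / sr
                    for m_i in fired_members:
                        member_spikes[p_i][m_i].append(t_now)
                current_n = float(pop.readout_weights @ trace.value) / pop.n_members
                states[k, p_i] = 1 if current_n >= pop.th_n else 0
        if mode == "streaming":
            wall[k] = time.perf_counter() - tic

    duration = (n_ticks - 1) / sr
    member_rasters = {}
    readout_trains = {}
    sign_policy = {}
    for p_i, pop in enumerate(pops):
        trains = [
            SpikeTrain(np.asarray(ts, dtype=float), duration)
            for ts in member_spikes[p_i]
        ]
        member_rasters[pop.label] = SpikeRaster(
            trains, [f"{pop.label}_span{m}" for m in range(pop.n_members)]
        )
        ticks = np.flatnonzero(states[:, p_i])
        readout_trains[pop.label] = SpikeTrain(ticks / sr, duration)
        sign_policy[pop.label] = "positive" if pop.decode_sign >= 0 else "negative"

    readout_raster = SpikeRaster(
        [readout_trains[p.label] for p in pops], [p.label for p in pops]
    )
    decoded = spike_codec.decode(
        readout_raster,
        model.thresholds_target,
        sr,
        n_samples=n_ticks,
        sign_policy=sign_policy,
    )
    return PredictionResult(
        member_rasters=member_rasters,
        readout_trains=readout_trains,
        readout_states=states,
        population_labels=[p.label for p in pops],
        decoded=decoded,
        reservoir_raster=sim.raster(duration),
        tick_wall_times=wall,
        sample_rate=sr,
    )


def predict_labels(
    result: PredictionResult,
    window_s: float,
    strategy: str = "mean",
) -> pd.DataFrame:
    """Per-window event-label decisions from the readout activity.

    ``strategy="mean"`` takes the argmax of the mean readout state over the
    window; ``"vote"`` counts, per population, the members that spiked in
    the window and takes the argmax.  Windows with no activity or with an
    exact tie get the no-event label.
    """
    if strategy not in ("mean", "vote"):
        raise ValueError("strategy must be 'mean' or 'vote'")
    sr = result.sample_rate
    n_ticks = result.readout_states.shape[0]
    w = max(int(round(window_s * sr)), 1)
    rows = []
    for start in range(0, n_ticks, w):
        stop = min(start + w, n_ticks)
        if strategy == "mean":
            scores = result.readout_states[start:stop].mean(axis=0)
        else:
            scores = np.array(
                [
                    sum(
                        np.any(
                            (tr.times >= start / sr) & (tr.times < stop / sr)
                        )
                        for tr in result.member_rasters[label].trains
                    )
                    for label in result.population_labels
                ],
                dtype=float,
            )
        top = scores.max() if scores.size else 0.0
        if top <= 0 or (scores == top).sum() > 1:
            label = NO_EVENT
        else:
            label = result.population_labels[int(np.argmax(scores))]
        rows.append({"t_start": start / sr, "t_end": stop / sr, "label": label})
    return pd.DataFrame(rows)
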