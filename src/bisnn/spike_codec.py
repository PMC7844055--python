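"""Threshold-based spike encoding and decoding of continuous signals.

A channel is encoded by thresholding the absolute difference between
consecutive samples: with ``d(t) = |x(t) - x(t-1)|`` the channel threshold is

    th = mean(d) + c * std(d)

where ``c`` is the encoding factor and ``std`` the population standard
deviation.  A spike is emitted at sample ``t`` (t >= 1) whenever
``d(t) >= th``, with the sign of ``x(t) - x(t-1)`` retained as polarity.
Decoding integrates the spikes back: starting from the stored initial value,
each spike steps the reconstruction by ``sign * th``.

The unsigned view of a raster (polarity dropped, every spike positive) is
what the supervised learning stage consumes; signs are kept internally so
signals can be reconstructed.  A channel whose samples never change has
``th = 0`` and encodes to an empty train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .signals import ContinuousSignal, SpikeRaster, SpikeTrain

__all__ = [
    "ChannelThreshold",
    "EncodingThresholds",
    "compute_threshold",
    "compute_thresholds",
    "encode",
    "decode",
]

#: default encoding factor when none is configured
DEFAULT_ENCODING_FACTOR = 0.5


@dataclass
class ChannelThreshold:
    """Per-channel encoding threshold plus the statistics behind it."""

    th: float
    c: float
    mean: float
    std: float
    initial: float

    def __post_init__(self) -> None:
        # th can come out negative for strongly negative c; clamp at zero so
        # the "reach the threshold" comparison stays meaningful.
        self.th = max(float(self.th), 0.0)


class EncodingThresholds:
    """Mapping of channel label -> :class:`ChannelThreshold` with JSON I/O."""

    def __init__(self, entries: dict[str, ChannelThreshold]):
        self.entries = dict(entries)

    def __getitem__(self, label: str) -> ChannelThreshold:
        return self.entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def to_dict(self) -> dict:
        return {
            label: {"th": e.th, "c": e.c, "mean": e.mean, "std": e.std, "initial": e.initial}
            for label, e in self.entries.items()
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingThresholds":
        return cls({label: ChannelThreshold(**v) for label, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "EncodingThresholds":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_threshold(x, c: float = DEFAULT_ENCODING_FACTOR) -> ChannelThreshold:
    """Compute one channel's encoding threshold from its samples.

    ``std`` is the population (divide-by-count) standard deviation of the
    absolute successive differences, so thresholds are reproducible across
    implementations.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("a channel needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite samples")
    d = np.abs(np.diff(x))
    mean = float(np.mean(d))
    std = float(np.std(d))  # population std
    return ChannelThreshold(th=mean + c * std, c=float(c), mean=mean, std=std, initial=float(x[0]))


def compute_thresholds(
    signal: ContinuousSignal, c: float | dict[str, float] = DEFAULT_ENCODING_FACTOR
) -> EncodingThresholds:
    """Thresholds for every channel of ``signal``; ``c`` scalar or per-channel."""
    entries = {}
    for j, label in enumerate(signal.channel_labels):
        cj = c[label] if isinstance(c, dict) else c
        entries[label] = compute_threshold(signal.values[:, j], cj)
    return EncodingThresholds(entries)


def encode(signal: ContinuousSignal, thresholds: EncodingThresholds) -> SpikeRaster:
    """Encode every channel into a signed spike train.

    A spike is emitted at sample index ``t >= 1`` when the absolute
    difference to the previous sample reaches the channel threshold
    (``>= th``); a zero threshold (constant channel) emits no spikes.  The
    spike is timestamped ``t / sample_rate``; the decision at sample ``t``
    uses samples up to ``t`` only, so encoding is causal and streamable.
    """
    missing = [l for l in signal.channel_labels if l not in thresholds]
    if missing:
        raise KeyError(f"no thresholds for channels: {missing}")
    duration = signal.duration
    trains = []
    for j, label in enumerate(signal.channel_labels):
        th = thresholds[label].th
        diff = np.diff(signal.values[:, j])
        if th <= 0.0:
            idx = np.array([], dtype=int)
        else:
            idx = np.flatnonzero(np.abs(diff) >= th)
        times = (idx + 1) / signal.sample_rate
        signs = np.where(diff[idx] >= 0, 1, -1).astype(int)
        trains.append(SpikeTrain(times, duration, signs))
    return SpikeRaster(trains, list(signal.channel_labels))


def decode(
    raster: SpikeRaster,
    thresholds: EncodingThresholds,
    sample_rate: float,
    n_samples: int | None = None,
    sign_policy: str | dict[str, str] = "signed",
    t0: float = 0.0,
) -> ContinuousSignal:
    """Reconstruct continuous signals from a spike raster.

    Starting from the channel's stored initial value, each spike steps the
    reconstruction by ``sign * th``.  For an unsigned raster the caller must
    opt into a constant-sign policy: ``"positive"`` (every spike adds
    ``+th``; the right choice for rectified, non-negative targets such as
    EMG envelopes) or ``"negative"``.  Decoding an unsigned train under the
    default ``"signed"`` policy is a configuration error.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if n_samples is None:
        n_samples = int(round(raster.duration * sample_rate)) + 1
    values = np.zeros((n_samples, raster.n_channels))
    for j, (label, train) in enumerate(zip(raster.labels, raster.trains)):
        entry = thresholds[label]
        policy = sign_policy[label] if isinstance(sign_policy, dict) else sign_policy
        if train.signs is not None and policy == "signed":
            signs = train.signs
        elif policy == "positive":
            signs = np.ones(train.n, dtype=int)
        elif policy == "negative":
            signs = -np.ones(train.n, dtype=int)
        elif train.signs is None:
            raise ValueError(
                f"channel {label!r}: unsigned train under 'signed' policy; "
                "opt into sign_policy='positive' explicitly"
            )
        else:
            raise ValueError(f"unknown sign policy {policy!r}")
        steps = np.zeros(n_samples)
        idx = np.round(train.times * sample_rate).astype(int)
        if np.any(idx >= n_samples) or np.any(idx < 0):
            raise ValueError("spike outside the requested sample grid")
        np.add.at(steps, idx, signs * entry.th)
        values[:, j] = entry.initial + np.cumsum(steps)
    return ContinuousSignal(values, sample_rate, list(raster.labels), t0)
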