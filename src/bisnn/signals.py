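"""Core containers: uniformly sampled multichannel signals and spike trains.

All spike times are expressed in seconds on the sample grid of the session
they belong to.  Sample ``k`` of a signal lives at time ``t0 + k / sample_rate``
with ``t0 = 0`` by default, so spike times and signal samples share one clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousSignal", "SpikeTrain", "SpikeRaster"]


@dataclass
class ContinuousSignal:
    """A uniformly sampled multichannel time series.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_channels)
        Real amplitudes, arbitrary units.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        One label per channel.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a (n_samples, n_channels) array")
        if self.values.shape[0] < 2:
            raise ValueError("a signal needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.values.shape[1]:
            raise ValueError("channel_labels length does not match values")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Time of the last sample relative to the first, in seconds."""
        return (self.n_samples - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        return self.values[:, self.channel_labels.index(label)]

    def select(self, labels: list[str]) -> "ContinuousSignal":
        idx = [self.channel_labels.index(l) for l in labels]
        return ContinuousSignal(self.values[:, idx], self.sample_rate, list(labels), self.t0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_labels)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ContinuousSignal":
        df = pd.read_csv(path)
        if df.shape[1] < 2 or df.shape[0] < 2:
            raise ValueError("signal CSV needs a time column, >=1 channel and >=2 rows")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time column is not uniformly sampled")
        return cls(
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            sample_rate=1.0 / dt[0],
            channel_labels=list(df.columns[1:]),
            t0=float(t[0]),
        )


@dataclass
class SpikeTrain:
    """An ordered set of spike times for one neuron or channel.

    ``signs`` is an optional per-spike polarity in {+1, -1}; a train without
    signs is *unsigned*, which is what the supervised (SPAN) stage consumes.
    """

    times: np.ndarray
    duration: float
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration + 1e-9):
            raise ValueError("spike times must lie within [0, duration]")
        if self.signs is not None:
            self.signs = np.asarray(self.signs, dtype=int)
            if self.signs.shape != self.times.shape:
                raise ValueError("signs must align with times")
            if self.signs.size and not np.all(np.isin(self.signs, (-1, 1))):
                raise ValueError("signs must be +1 or -1")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def is_signed(self) -> bool:
        return self.signs is not None

    def unsigned(self) -> "SpikeTrain":
        """Drop polarity: identical times, no signs."""
        return SpikeTrain(self.times.copy(), self.duration, None)

    def shifted(self, offset: float, duration: float | None = None) -> "SpikeTrain":
        return SpikeTrain(
            self.times + offset,
            self.duration if duration is None else duration,
            None if self.signs is None else self.signs.copy(),
        )

    def window(self, start: float, end: float) -> "SpikeTrain":
        """Spikes in [start, end), re-referenced to ``start``."""
        m = (self.times >= start) & (self.times < end)
        return SpikeTrain(
            self.times[m] - start,
            end - start,
            None if self.signs is None else self.signs[m],
        )


@dataclass
class SpikeRaster:
    """An ordered collection of spike trains sharing one duration."""

    trains: list[SpikeTrain]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.trains))]
        if len(self.labels) != len(self.trains):
            raise ValueError("labels must align with trains")
        durs = {t.duration for t in self.trains}
        if len(durs) > 1:
            raise ValueError("all trains must share one duration")

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration if self.trains else 0.0

    @property
    def total_spikes(self) -> int:
        return sum(t.n for t in self.trains)

    def train(self, label: str) -> SpikeTrain:
        return self.trains[self.labels.index(label)]

    def unsigned(self) -> "SpikeRaster":
        return SpikeRaster([t.unsigned() for t in self.trains], list(self.labels))

    def window(self, start: float, end: float) -> "SpikeRaster":
        return SpikeRaster([t.window(start, end) for t in self.trains], list(self.labels))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, tr in zip(self.labels, self.trains):
            for k in range(tr.n):
                rows.append(
                    {
                        "channel_label": label,
                        "spike_time_s": tr.times[k],
                        "sign": int(tr.signs[k]) if tr.signs is not None else "",
                    }
                )
        return pd.DataFrame(rows, columns=["channel_label", "spike_time_s", "sign"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float, labels: list[str] | None = None) -> "SpikeRaster":
        df = pd.read_csv(path, dtype={"channel_label": str})
        has_sign = "sign" in df.columns and df["sign"].notna().any()
        if labels is None:
            labels = sorted(df["channel_label"].unique())
        trains = []
        for label in labels:
            sub = df[df["channel_label"] == label].sort_values("spike_time_s")
            signs = sub["sign"].to_numpy(dtype=int) if has_sign else None
            trains.append(SpikeTrain(sub["spike_time_s"].to_numpy(dtype=float), duration, signs))
        return cls(trains, list(labels))
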