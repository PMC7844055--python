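"""Seeded synthetic sessions: EEG-like inputs and correlated motor targets.

A session emulates the event-locked structure of a cued grasp-and-lift
experiment: trials occur at regular intervals (with onset jitter), each
trial triggers band-limited oscillatory bursts in a handful of latent
cortical "sources", and every input channel records a gain-weighted mixture
of the sources plus white noise at a configured SNR.  Target channels
causally follow the trial onsets: EMG-like targets are rectified
rise-plateau-fall envelopes, kinematics-like targets are smooth trapezoids
(position-like) or wrapped-phase ramps (angle-like).

Channel gains mirror the montage geometry: channels placed nearest a
source's scalp location receive the largest gain, so mapping channels into
the 3D reservoir is meaningful on synthetic data.  All randomness flows
from the single seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signals import ContinuousSignal

__all__ = ["SynthConfig", "SynthSession", "generate_session", "shuffled_control"]

# scalp anchor directions (unit vectors, x right / y anterior / z superior)
# for the latent sources; scaled onto the head ellipsoid at build time
_SOURCE_DIRECTIONS = np.array(
    [
        [-0.55, 0.55, 0.63],   # left fronto-central
        [0.55, 0.55, 0.63],    # right fronto-central
        [-0.55, -0.55, 0.63],  # left centro-parietal
        [0.55, -0.55, 0.63],   # right centro-parietal
        [0.0, 0.9, 0.44],      # frontal midline
        [0.0, -0.9, 0.44],     # parietal midline
    ]
)


@dataclass
class SynthConfig:
    """Generation parameters; defaults are the package's study conditions."""

    n_channels_in: int = 8
    n_emg: int = 2
    n_kinematic: int = 2
    kinematic_kind: str = "position"  # or "angle" (wrapped-phase ramp)
    sample_rate: float = 100.0
    n_trials: int = 20
    trial_length: float = 2.0
    inter_trial_gap: float = 1.0
    carrier_band: tuple[float, float] = (10.0, 30.0)
    snr: float = 5.0
    n_sources: int = 4
    burst_width: float = 0.5
    gain_sigma: float = 45.0      # mm; spatial spread of source-to-channel gain
    onset_jitter: float = 0.05
    target_lag: float = 0.1       # s; targets causally follow the onset
    semi_axes: tuple[float, float, float] = (60.0, 80.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_channels_in, self.n_emg + self.n_kinematic) < 1:
            raise ValueError("need at least one input and one target channel")
        if self.sample_rate <= 0 or self.snr <= 0:
            raise ValueError("sample_rate and snr must be positive")
        if self.n_trials < 0 or self.trial_length <= 0 or self.inter_trial_gap < 0:
            raise ValueError("invalid trial layout")
        if self.n_sources > len(_SOURCE_DIRECTIONS):
            raise ValueError(f"at most {len(_SOURCE_DIRECTIONS)} sources supported")
        if self.kinematic_kind not in ("position", "angle"):
            raise ValueError("kinematic_kind must be 'position' or 'angle'")

    @property
    def duration(self) -> float:
        period = self.trial_length + self.inter_trial_gap
        return self.inter_trial_gap + max(self.n_trials, 1) * period

    @property
    def target_labels(self) -> list[str]:
        return [f"emg{j}" for j in range(self.n_emg)] + [
            f"kin{j}" for j in range(self.n_kinematic)
        ]


@dataclass
class SynthSession:
    """One generated session with its ground truth."""

    inputs: ContinuousSignal
    targets: ContinuousSignal
    events: np.ndarray            # trial onset times, seconds
    montage: pd.DataFrame         # label, x, y, z for the input channels
    config: SynthConfig
    envelopes: ContinuousSignal | None = None  # noiseless generating envelopes

    @property
    def trial_windows(self) -> list[tuple[float, float]]:
        """(start, end) of each trial window, onset to onset + trial period."""
        span = self.config.trial_length + self.config.inter_trial_gap
        return [(float(t), float(t) + span) for t in self.events]

    def first_trials(self, k: int) -> "SynthSession":
        """The session truncated after its first ``k`` trials."""
        if k > len(self.events):
            raise ValueError("fewer trials in the session than requested")
        sr = self.config.sample_rate
        end = self.trial_windows[k - 1][1] if k > 0 else self.config.inter_trial_gap
        n = min(int(round(end * sr)) + 1, self.inputs.n_samples)
        cut = lambda sig: ContinuousSignal(
            sig.values[:n], sr, list(sig.channel_labels), sig.t0
        )
        return SynthSession(
            cut(self.inputs),
            cut(self.targets),
            self.events[:k],
            self.montage,
            replace(self.config, n_trials=k),
            cut(self.envelopes) if self.envelopes is not None else None,
        )


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh((t - t0) / max(width, 1e-9)))


def _emg_envelope(t: np.ndarray, onset: float, length: float) -> np.ndarray:
    """Rectified rise-plateau-fall bump starting at ``onset``."""
    rise = _smoothstep(t, onset + 0.15, 0.04)
    fall = _smoothstep(t, onset + length - 0.35, 0.05)
    return np.clip(rise - fall, 0.0, None)


def _position_profile(t: np.ndarray, onset: float, length: float) -> np.ndarray:
    """Smooth sigmoid rise then fall (reach, hold, replace)."""
    up = _smoothstep(t, onset + 0.3, 0.15)
    down = _smoothstep(t, onset + length - 0.3, 0.15)
    return up - down


def _angle_profile(t: np.ndarray, onset: float, length: float, sr: float) -> np.ndarray:
    """Wrapped-phase ramp during the trial, zero outside."""
    active = (t >= onset) & (t < onset + length)
    phase = np.zeros_like(t)
    ramp = 2.0 * np.pi * 0.8 * (t[active] - onset)
    phase[active] = np.angle(np.exp(1j * ramp))
    return phase / np.pi  # keep amplitudes O(1)


def generate_session(config: SynthConfig, seed: int | None = None) -> SynthSession:
    """Generate one seeded session (inputs, targets, events, montage)."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sample_rate
    n = int(round(cfg.duration * sr)) + 1
    t = np.arange(n) / sr
    period = cfg.trial_length + cfg.inter_trial_gap

    onsets = np.array(
        [
            cfg.inter_trial_gap + k * period + rng.uniform(-cfg.onset_jitter, cfg.onset_jitter)
            for k in range(cfg.n_trials)
        ]
    )

    # ---- latent sources: event-locked oscillatory bursts -----------------
    a, b, c = cfg.semi_axes
    src_pos = _SOURCE_DIRECTIONS[: cfg.n_sources] * np.array([a, b, c])
    f_lo, f_hi = cfg.carrier_band
    src_freq = rng.uniform(f_lo, f_hi, size=cfg.n_sources)
    src_delay = np.linspace(0.0, 0.3, cfg.n_sources)
    half = cfg.burst_width / 2.0
    sources = np.zeros((n, cfg.n_sources))
    for s in range(cfg.n_sources):
        for onset in onsets:
            t0 = onset + src_delay[s]
            phase = rng.uniform(0, 2 * np.pi)
            rel = t - (t0 + half)
            env = np.where(
                np.abs(rel) <= half, 0.5 * (1 + np.cos(np.pi * rel / half)), 0.0
            )  # Hanning bump of burst_width seconds
            sources[:, s] += env * np.sin(2 * np.pi * src_freq[s] * t + phase)

    # ---- montage: channels scattered around their dominant source --------
    ch_labels = [f"ch{i:02d}" for i in range(cfg.n_channels_in)]
    ch_pos = np.empty((cfg.n_channels_in, 3))
    for i in range(cfg.n_channels_in):
        anchor = src_pos[i % cfg.n_sources]
        jitter = rng.normal(0.0, 6.0, size=3)
        p = anchor + jitter
        # re-project onto the ellipsoid surface so channels stay on the scalp
        scale = 1.0 / np.sqrt((p[0] / a) ** 2 + (p[1] / b) ** 2 + (p[2] / c) ** 2)
        ch_pos[i] = p * scale
    montage = pd.DataFrame(
        {"label": ch_labels, "x": ch_pos[:, 0], "y": ch_pos[:, 1], "z": ch_pos[:, 2]}
    )

    gains = np.exp(
        -np.linalg.norm(ch_pos[:, None, :] - src_pos[None, :, :], axis=-1) ** 2
        / (2 * cfg.gain_sigma**2)
    )

    mixture = sources @ gains.T
    rms = np.sqrt(np.mean(mixture**2, axis=0))
    noise_std = np.where(rms > 0, rms / cfg.snr, 1.0 / cfg.snr)
    inputs_vals = mixture + rng.normal(0.0, 1.0, size=mixture.shape) * noise_std

    # ---- targets ---------------------------------------------------------
    labels = cfg.target_labels
    tgt = np.zeros((n, len(labels)))
    for j in range(cfg.n_emg):
        lag = cfg.target_lag + 0.05 * j
        for onset in onsets:
            tgt[:, j] += _emg_envelope(t, onset + lag, cfg.trial_length)
    for j in range(cfg.n_kinematic):
        col = cfg.n_emg + j
        lag = cfg.target_lag + 0.05 * j
        for onset in onsets:
            if cfg.kinematic_kind == "angle":
                tgt[:, col] += _angle_profile(t, onset + lag, cfg.trial_length, sr)
            else:
                tgt[:, col] += _position_profile(t, onset + lag, cfg.trial_length)

    inputs = ContinuousSignal(inputs_vals, sr, ch_labels)
    targets = ContinuousSignal(tgt, sr, labels)
    envelopes = ContinuousSignal(tgt.copy(), sr, labels)
    return SynthSession(inputs, targets, onsets, montage, cfg, envelopes)


def shuffled_control(session: SynthSession, seed: int) -> SynthSession:
    """Break input-target alignment by circularly shifting each target.

    Each target channel is rolled by an independent random offset of at
    least one trial length, preserving its marginal distribution; inputs,
    events and montage are returned untouched.
    """
    if session.config.n_trials < 2:
        raise ValueError("shuffled control needs at least 2 trials")
    rng = np.random.default_rng(seed)
    n = session.targets.n_samples
    min_off = int(round(session.config.trial_length * session.targets.sample_rate))
    vals = session.targets.values.copy()
    for j in range(vals.shape[1]):
        off = int(rng.integers(min_off, n - min_off))
        vals[:, j] = np.roll(vals[:, j], off)
    shuffled = ContinuousSignal(
        vals, session.targets.sample_rate, list(session.targets.channel_labels)
    )
    return SynthSession(
        session.inputs, shuffled, session.events, session.montage, session.config,
        session.envelopes,
    )
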