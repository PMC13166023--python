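"""Seeded generator of workload-labelled multichannel EEG epochs.

Each channel is a sum of narrowband oscillators at the canonical EEG
rhythms — δ ≈ 2 Hz, θ ≈ 6 Hz, α ≈ 10 Hz, β ≈ 20 Hz — with random phase,
mild frequency jitter (±0.5 Hz), and slow Hann-windowed amplitude bursts,
on top of 1/f^β background noise. Workload is encoded the way N-back load
manifests in real EEG: frontal-midline θ amplitude increases with load
(theta_gain per condition, applied on frontal channels) and posterior α
decreases (alpha_gain, applied on posterior channels). A per-subject
multiplicative amplitude factor models between-subject gain variability.

The oscillators are bursty rather than pure tones so that EMD produces
realistic, non-degenerate modes. The generator makes no attempt at forward
head modelling, realistic electrode geometry, or artifact simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

__all__ = ["SynthConfig", "EpochedEEG", "generate_dataset", "generate_epoch"]


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: (epochs × channels × samples) in µV."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    subject_ids: np.ndarray
    channel_names: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("label count must equal epoch count")
        if self.subject_ids.shape[0] != self.data.shape[0]:
            raise ValueError("subject_id count must equal epoch count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class SynthConfig:
    """Study-condition settings for the generator.

    Defaults emulate a three-level N-back protocol: 1000 Hz sampling, 3 s
    epochs, conditions 0-/2-/3-back with frontal θ gain rising and posterior
    α gain falling with load. Eight channels (three frontal, three posterior)
    keep desk-scale runs cheap; pass n_channels=64 for a full-montage layout.
    """

    n_channels: int = 8
    fs: float = 1000.0
    epoch_seconds: float = 3.0
    n_epochs_per_condition: int = 50
    conditions: tuple = ("0-back", "2-back", "3-back")
    theta_gain: tuple = (1.0, 1.5, 2.0)
    alpha_gain: tuple = (1.0, 0.8, 0.65)
    delta_amp: float = 0.7
    theta_amp: float = 1.0
    alpha_amp: float = 1.0
    beta_amp: float = 0.4
    noise_amp: float = 1.0
    noise_exponent: float = 1.0
    subject_scale_sd: float = 0.2
    n_subjects: int = 5
    seed: int = 0
    frontal_channels: tuple = (0, 1, 2)
    posterior_channels: tuple = (5, 6, 7)
    global_scale_uv: float = 10.0  # overall amplitude scale in µV

    def __post_init__(self) -> None:
        n_cond = len(self.conditions)
        if len(self.theta_gain) != n_cond or len(self.alpha_gain) != n_cond:
            raise ValueError("per-condition gains must match the number of conditions")
        if any(g <= 0 for g in self.theta_gain) or any(g <= 0 for g in self.alpha_gain):
            raise ValueError("all gains must be positive")
        if self.fs * self.epoch_seconds < 512:
            raise ValueError("fs * epoch_seconds must be >= 512 samples")
        if max(self.frontal_channels, default=-1) >= self.n_channels:
            raise ValueError("frontal channel index out of range")
        if max(self.posterior_channels, default=-1) >= self.n_channels:
            raise ValueError("posterior channel index out of range")
        if self.n_subjects < 1 or self.n_epochs_per_condition < 1:
            raise ValueError("n_subjects and n_epochs_per_condition must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    def channel_names(self) -> list:
        names = []
        for c in range(self.n_channels):
            if c in self.frontal_channels:
                names.append(f"F{c}")
            elif c in self.posterior_channels:
                names.append(f"P{c}")
            else:
                names.append(f"C{c}")
        return names


#: Center frequencies (Hz) of the simulated rhythms.
_RHYTHM_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}


def _burst_envelope(n: int, rng: np.random.Generator) -> np.ndarray:
    """Slow amplitude modulation: a baseline plus 1–3 Hann-windowed bursts."""
    env = np.full(n, 0.6)
    for _ in range(rng.integers(1, 4)):
        width = int(n * rng.uniform(0.2, 0.6))
        start = rng.integers(0, max(1, n - width))
        env[start:start + width] += 0.4 * hann(width)
    return np.clip(env, 0.0, 1.2)


def _oscillator(n: int, fs: float, f0: float, rng: np.random.Generator) -> np.ndarray:
    """Random-phase sinusoid with ±0.5 Hz jitter under a bursty envelope."""
    f = f0 + rng.uniform(-0.5, 0.5)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return _burst_envelope(n, rng) * np.sin(2 * np.pi * f * t + phase)


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_epoch(condition, subject_factor: float, config: SynthConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One (channels × samples) epoch for a named condition."""
    if condition not in config.conditions:
        raise ValueError(f"unknown condition label {condition!r}")
    ci = config.conditions.index(condition)
    n = config.n_samples
    out = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        theta_g = config.theta_gain[ci] if c in config.frontal_channels else 1.0
        alpha_g = config.alpha_gain[ci] if c in config.posterior_channels else 1.0
        sig = (
            config.delta_amp * _oscillator(n, config.fs, _RHYTHM_FREQS["delta"], rng)
            + config.theta_amp * theta_g * _oscillator(n, config.fs, _RHYTHM_FREQS["theta"], rng)
            + config.alpha_amp * alpha_g * _oscillator(n, config.fs, _RHYTHM_FREQS["alpha"], rng)
            + config.beta_amp * _oscillator(n, config.fs, _RHYTHM_FREQS["beta"], rng)
        )
        if config.noise_amp > 0:
            sig = sig + config.noise_amp * _one_over_f_noise(n, config.noise_exponent, rng)
        out[c] = sig
    return out * subject_factor * config.global_scale_uv


def generate_dataset(config: SynthConfig) -> EpochedEEG:
    """Full labelled dataset, deterministic per config.seed.

    Epochs within each condition are assigned to subjects round-robin; each
    subject carries one multiplicative lognormal amplitude factor
    (sd = subject_scale_sd on the log scale).
    """
    rng = np.random.default_rng(config.seed)
    subject_factors = np.exp(rng.normal(0.0, config.subject_scale_sd, config.n_subjects))
    n_total = config.n_epochs_per_condition * len(config.conditions)
    data = np.empty((n_total, config.n_channels, config.n_samples))
    labels = []
    subject_ids = []
    i = 0
    for ci, cond in enumerate(config.conditions):
        for j in range(config.n_epochs_per_condition):
            s = j % config.n_subjects
            data[i] = generate_epoch(cond, float(subject_factors[s]), config, rng)
            labels.append(cond)
            subject_ids.append(s)
            i += 1
    return EpochedEEG(data=data, fs=config.fs, labels=np.asarray(labels),
                      subject_ids=np.asarray(subject_ids),
                      channel_names=config.channel_names())
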