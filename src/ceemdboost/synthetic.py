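"""Synthetic EEG-like segments with controllable seizure/background contrast.

Background activity is 1/f^β (pink) noise plus an alpha-band (8–13 Hz)
oscillation, which mimics the broadband, rhythmically tinged character of
awake scalp EEG.  Seizure segments add a high-amplitude 3–5 Hz spike-wave
train (fundamental plus two harmonics) on top of the same background,
echoing the low-frequency rhythmic discharges that dominate ictal
recordings.  Everything is deterministic under a seed, so the full
pipeline is testable without downloading clinical data.

These surrogates capture amplitude and spectral contrast only — no
electrode artifacts, no inter-patient variability, no seizure evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_io import SegmentSet, Signal

__all__ = [
    "SynthConfig",
    "gen_background",
    "gen_seizure",
    "gen_dataset",
    "standard_benchmark",
]

ALPHA_BAND = (8.0, 13.0)  # Hz
SPIKE_BAND = (3.0, 5.0)  # Hz


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``seizure_multiplier`` scales the spike-wave train to that multiple of
    the background standard deviation; values well above 1 give separable
    benchmarks.  ``pink_exponent`` is β of the 1/f^β background spectrum.
    """

    rate: float = 256.0
    duration_s: float = 3.0
    n_channels: int = 1
    n_per_class: int = 100
    pink_exponent: float = 1.0
    alpha_amplitude: float = 1.0
    noise_sd: float = 1.0
    seizure_multiplier: float = 4.0
    harmonic_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.rate <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")
        if self.n_channels < 1 or self.n_per_class < 1:
            raise ValueError("channel and segment counts must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration_s))


def standard_benchmark(seed: int = 7, n_per_class: int = 100) -> SynthConfig:
    """The single-channel 3-s/256-Hz benchmark used throughout the tests."""
    return SynthConfig(
        rate=256.0,
        duration_s=3.0,
        n_channels=1,
        n_per_class=n_per_class,
        seizure_multiplier=4.0,
        seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n: int, beta: float, sd: float) -> np.ndarray:
    """1/f^β noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    scale = x.std()
    return x / scale * sd if scale > 0 else x


def _background_channel(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    n = cfg.n_samples
    t = np.arange(n) / cfg.rate
    x = _pink_noise(rng, n, cfg.pink_exponent, cfg.noise_sd)
    if cfg.alpha_amplitude > 0:
        freq = rng.uniform(*ALPHA_BAND)
        phase = rng.uniform(0, 2 * np.pi)
        x = x + cfg.alpha_amplitude * np.sin(2 * np.pi * freq * t + phase)
    return x


def _spike_wave(rng: np.random.Generator, cfg: SynthConfig, target_sd: float) -> np.ndarray:
    n = cfg.n_samples
    t = np.arange(n) / cfg.rate
    fundamental = rng.uniform(*SPIKE_BAND)
    train = np.zeros(n)
    for h in range(3):  # fundamental + 2 harmonics
        phase = rng.uniform(0, 2 * np.pi)
        train += cfg.harmonic_decay**h * np.sin(2 * np.pi * fundamental * (h + 1) * t + phase)
    sd = train.std()
    return train / sd * target_sd if sd > 0 else train


def gen_background(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Signal:
    """One non-seizure segment: pink noise + alpha oscillation per channel."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    data = np.stack([_background_channel(rng, cfg) for _ in range(cfg.n_channels)])
    channels = tuple(f"ch{i + 1}" for i in range(cfg.n_channels))
    return Signal(data, rate=cfg.rate, channels=channels)


def gen_seizure(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Signal:
    """One seizure segment: background plus a scaled 3–5 Hz spike-wave train."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    for _ in range(cfg.n_channels):
        bg = _background_channel(rng, cfg)
        target = cfg.seizure_multiplier * bg.std()
        rows.append(bg + _spike_wave(rng, cfg, target))
    channels = tuple(f"ch{i + 1}" for i in range(cfg.n_channels))
    return Signal(np.stack(rows), rate=cfg.rate, channels=channels)


def gen_dataset(cfg: SynthConfig) -> SegmentSet:
    """Balanced labeled segments: ``n_per_class`` of each class, seeded.

    Segment RNG streams are spawned per segment, so any one segment is
    reproducible independently of how many are generated.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(2 * cfg.n_per_class)
    segments: list[Signal] = []
    labels: list[str] = []
    for i in range(cfg.n_per_class):
        rng = np.random.default_rng(children[2 * i])
        segments.append(gen_background(cfg, rng))
        labels.append("non-seizure")
        rng = np.random.default_rng(children[2 * i + 1])
        segments.append(gen_seizure(cfg, rng))
        labels.append("seizure")
    return SegmentSet(segments, labels, window_s=cfg.duration_s)
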