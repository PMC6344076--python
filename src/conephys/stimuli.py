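"""Light-stimulus waveform construction.

Stimuli are expressed as photon-absorption rates (R*/cone/s) over time:
brief flashes on a steady background, sinusoids whose contrast is
amplitude/mean, and band-limited Gaussian noise whose contrast is SD/mean
(default 50% contrast, 0-60 Hz bandwidth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Stimulus",
    "sinusoid_stimulus",
    "gaussian_noise_stimulus",
    "flash_stimulus",
]

STIMULUS_KINDS = ("flash", "step", "sinusoid", "gaussian_noise")


@dataclass
class Stimulus:
    """Parametric stimulus description.

    contrast is SD/mean for gaussian_noise and amplitude/mean for sinusoid.
    bandwidth is the upper edge (Hz) of the noise band, lower edge 0.
    """

    kind: str
    mean_level: float
    duration: float
    sampling_rate: float = 10_000.0
    contrast: float = 0.0
    frequency: float = 0.0
    bandwidth: float = 60.0
    seed: int | None = None
    flash_duration: float = 0.010
    flash_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.contrast < 0 or self.mean_level < 0:
            raise ValueError("contrast and mean_level must be nonnegative")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def waveform(self) -> np.ndarray:
        """Sampled waveform in R*/s for any stimulus kind."""
        if self.kind == "sinusoid":
            return sinusoid_stimulus(self)
        if self.kind == "gaussian_noise":
            return gaussian_noise_stimulus(self)
        if self.kind == "flash":
            return flash_stimulus(self)
        if self.kind == "step":
            return np.full(self.n_samples, self.mean_level)
        raise AssertionError


def sinusoid_stimulus(spec: Stimulus) -> np.ndarray:
    """mean * (1 + contrast * sin(2 pi f t)); clipping at zero is logged."""
    if spec.frequency >= spec.sampling_rate / 2:
        raise ValueError("sinusoid frequency must be below Nyquist")
    t = spec.times()
    wave = spec.mean_level * (1.0 + spec.contrast * np.sin(2 * np.pi * spec.frequency * t))
    if spec.contrast > 1:
        n_neg = int(np.sum(wave < 0))
        logger.warning(
            "sinusoid contrast %.2f > 1: clipping %d negative samples", spec.contrast, n_neg
        )
        wave = np.clip(wave, 0.0, None)
    return wave


def gaussian_noise_stimulus(spec: Stimulus) -> np.ndarray:
    """Band-limited Gaussian noise with exact SD = contrast * mean.

    White Gaussian noise is masked in the frequency domain to [0, bandwidth]
    (hard mask, DC excluded) and rescaled to the target SD.  Negative light
    is clipped and logged — with the default 50% contrast clipping is rare
    (mean is 2 SD above zero).
    """
    if spec.bandwidth > spec.sampling_rate / 2:
        raise ValueError("noise bandwidth must not exceed Nyquist")
    n = spec.n_samples
    if spec.contrast == 0:
        return np.full(n, spec.mean_level)
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    spec_f = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    mask = (freqs > 0) & (freqs <= spec.bandwidth)
    spec_f[~mask] = 0.0
    band = np.fft.irfft(spec_f, n=n)
    sd = band.std()
    if sd == 0:
        raise ValueError("noise band empty; increase duration or bandwidth")
    wave = spec.mean_level + band / sd * (spec.contrast * spec.mean_level)
    n_neg = int(np.sum(wave < 0))
    if n_neg:
        frac = n_neg / n
        # a few percent of samples clip at the default 50% contrast (the mean
        # sits 2 SD above zero); flag loudly only when clipping is heavy
        log = logger.warning if frac > 0.05 else logger.info
        log("gaussian noise stimulus: clipping %d negative samples (%.1f%%)",
            n_neg, 100 * frac)
        wave = np.clip(wave, 0.0, None)
    return wave


def flash_stimulus(spec: Stimulus, flash_time: float = 0.0) -> np.ndarray:
    """Steady background with a brief increment of ``flash_strength`` R*/s."""
    wave = np.full(spec.n_samples, spec.mean_level)
    i0 = int(round(flash_time * spec.sampling_rate))
    i1 = i0 + max(1, int(round(spec.flash_duration * spec.sampling_rate)))
    wave[i0:i1] += spec.flash_strength
    return wave
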