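"""In-memory containers for electrophysiological traces and spike trains."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Recording", "SpikeTrain"]

MODALITIES = ("current", "voltage", "spikes")
CONE_TYPES = ("S", "M", "L", "unknown")


@dataclass
class Recording:
    """One trace or trial block with its acquisition metadata.

    samples : 1-D array (single trace) or 2-D array (trials x time).
    sampling_rate : Hz.
    modality : 'current' (pA), 'voltage' (mV) or 'spikes' (extracellular).
    background : steady photon-absorption rate, R*/cone/s.
    cone_type : 'S' | 'M' | 'L' | 'unknown'.
    stimulus : optional description or waveform of the stimulus delivered.
    """

    samples: np.ndarray
    sampling_rate: float
    modality: str = "current"
    background: float = 0.0
    cone_type: str = "unknown"
    retina_id: str = ""
    cell_id: str = ""
    units: str = "pA"
    stimulus: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.cone_type not in CONE_TYPES:
            raise ValueError(f"unknown cone_type {self.cone_type!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_trials(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def trial_average(self) -> "Recording":
        """Average across trials (no-op for a single trace)."""
        if self.samples.ndim == 1:
            return self
        out = Recording(**{**self.__dict__, "samples": self.samples.mean(axis=0)})
        out.meta = dict(self.meta, n_trials=self.samples.shape[0])
        return out


@dataclass
class SpikeTrain:
    """Spike times (s) with an optional binary per-bin representation."""

    times: np.ndarray
    bin_width: float = 1e-3
    duration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(self.times < 0) or np.any(np.diff(self.times) < 0)):
            raise ValueError("spike times must be nonnegative and sorted")
        if self.duration is None:
            self.duration = float(self.times[-1] + self.bin_width) if self.times.size else 0.0

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def to_binary(self, duration: float | None = None) -> np.ndarray:
        """Binary per-bin spike indicator vector."""
        dur = self.duration if duration is None else duration
        n = int(round(dur / self.bin_width))
        vec = np.zeros(n)
        idx = np.minimum((self.times / self.bin_width).astype(int), n - 1)
        vec[idx] = 1.0
        return vec

    @classmethod
    def from_binary(cls, vec: np.ndarray, bin_width: float) -> "SpikeTrain":
        idx = np.flatnonzero(np.asarray(vec) > 0)
        return cls(times=idx * bin_width + bin_width / 2, bin_width=bin_width,
                   duration=len(vec) * bin_width)
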