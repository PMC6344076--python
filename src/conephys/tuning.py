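"""Temporal frequency tuning: sinusoid fits, tuning curves, model spectra.

A cone's response amplitude at each stimulus frequency comes from a
least-squares sinusoid fit (frequency fixed to the stimulus), divided by the
stimulus contrast — higher contrasts are needed at high frequencies, and the
division makes amplitudes comparable.  Per-cell curves are normalised to
unit maximum before averaging.  Under linearity the tuning curve has the
shape of the flash response's spectrum, so curves are fitted with the
flash-template power spectrum under a squared-log-ratio loss, and summarised
by the frequency at which the fitted curve falls to 10% of its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .recording import Recording
from .template import FlashTemplateParams, template_power_spectrum

__all__ = [
    "SinusoidFit",
    "TuningCurve",
    "TuningFit",
    "fit_sinusoid",
    "build_tuning_curve",
    "fit_tuning_model",
    "cutoff_frequency",
]


@dataclass
class SinusoidFit:
    """Least-squares fit y = a sin(2 pi f x + b) + c at fixed frequency f.

    ``amplitude`` is the contrast-normalised response amplitude a/contrast.
    """

    a: float
    b: float
    c: float
    f: float
    contrast: float

    @property
    def amplitude(self) -> float:
        return self.a / self.contrast


@dataclass
class TuningCurve:
    """Normalised response amplitude vs frequency (unit maximum)."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    sem: np.ndarray | None = None
    n_cells: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class TuningFit:
    """Fitted model spectrum and its 10%-of-maximum cutoff."""

    theta: FlashTemplateParams
    cutoff_10pct: float
    loss_value: float
    dense_freqs: np.ndarray
    dense_curve: np.ndarray  # normalised to unit maximum
    spectrum_kind: str = "power"
    extrapolated: bool = False


def fit_sinusoid(
    trace,
    f: float,
    contrast: float,
    sampling_rate: float | None = None,
) -> SinusoidFit:
    """Exact linear least-squares sinusoid fit with fixed frequency.

    The amplitude is canonicalised nonnegative (sign folded into the phase).
    """
    if isinstance(trace, Recording):
        y, fs = trace.trial_average().samples, trace.sampling_rate
    else:
        y, fs = np.asarray(trace, dtype=float), sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for array input")
    if f >= fs / 2:
        raise ValueError("stimulus frequency must be below Nyquist")
    t = np.arange(len(y)) / fs
    if t[-1] < 3.0 / f:
        raise ValueError("trace must cover at least 3 stimulus periods")
    design = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t),
                              np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    s_coef, c_coef, offset = coef
    a = float(np.hypot(s_coef, c_coef))
    b = float(np.arctan2(c_coef, s_coef))
    return SinusoidFit(a=a, b=b, c=float(offset), f=f, contrast=contrast)


def build_tuning_curve(fits_per_cell: list[list[SinusoidFit]]) -> TuningCurve:
    """Population tuning curve from per-cell sinusoid fits.

    Each cell's contrast-normalised amplitudes are scaled to unit maximum
    before averaging; the population curve is then renormalised to unit
    maximum with mean ± sem across cells.
    """
    if not fits_per_cell:
        raise ValueError("no cells provided")
    freqs = np.array(sorted(f.f for f in fits_per_cell[0]))
    if len(freqs) < 3:
        raise ValueError("need at least 3 frequencies")
    per_cell = []
    for fits in fits_per_cell:
        by_f = {fit.f: fit.amplitude for fit in fits}
        if sorted(by_f) != list(freqs):
            raise ValueError("cells must share the same frequency set")
        amps = np.array([by_f[f] for f in freqs])
        if amps.max() == 0:
            raise ValueError("all-zero amplitudes for one cell")
        per_cell.append(amps / amps.max())
    per_cell = np.array(per_cell)
    mean = per_cell.mean(axis=0)
    sem = per_cell.std(axis=0, ddof=1) / np.sqrt(len(per_cell)) if len(per_cell) > 1 else None
    scale = mean.max()
    return TuningCurve(
        frequencies=freqs,
        amplitudes=mean / scale,
        sem=None if sem is None else sem / scale,
        n_cells=len(per_cell),
    )


def _model_curve(theta: FlashTemplateParams, freqs: np.ndarray, dense: np.ndarray,
                 kind: str, dt_ms: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Normalised model spectrum at probe and dense frequencies."""
    both = template_power_spectrum(theta, np.concatenate([freqs, dense]), dt_ms)
    if kind == "amplitude":
        both = np.sqrt(both)
    spec_probe, spec_dense = both[: len(freqs)], both[len(freqs):]
    peak = spec_dense.max()
    if not np.isfinite(peak) or peak <= 0:
        tiny = np.full_like(spec_probe, 1e-300)
        return tiny, np.full_like(spec_dense, 1e-300)
    return spec_probe / peak, spec_dense / peak


def fit_tuning_model(
    curve: TuningCurve,
    spectrum: str = "power",
    f_max: float = 120.0,
    n_dense: int = 1201,
) -> TuningFit:
    """Fit the flash-template spectrum to a tuning curve.

    ``spectrum='power'`` fits the squared amplitude spectrum of the template
    (the default reading of "power spectrum of the flash response");
    ``'amplitude'`` fits the amplitude spectrum instead.  Both model and
    data are normalised to unit maximum and compared with the loss
    sum_i [log(F(w_i)/D(w_i))]^2.
    """
    if spectrum not in ("power", "amplitude"):
        raise ValueError("spectrum must be 'power' or 'amplitude'")
    D = curve.amplitudes
    if np.any(D <= 0):
        raise ValueError("tuning amplitudes must be positive for the log-ratio loss")
    freqs = curve.frequencies
    dense = np.linspace(0.0, f_max, n_dense)
    coarse = np.linspace(0.0, f_max, 121)  # cheap normalisation grid for the solver

    def residual(x):
        tr, tosc = np.exp(x)
        theta = FlashTemplateParams(1.0, tr, tr, tosc, -np.pi / 4)
        model, _ = _model_curve(theta, freqs, coarse, spectrum)
        r = np.log(np.maximum(model, 1e-300) / D)
        # free amplitude scale solved analytically: the loss compares shapes,
        # so a common multiplier on the data cannot change the fit
        return r - r.mean()

    best = None
    for tr0 in (15.0, 30.0, 60.0):
        for to0 in (120.0, 300.0):
            try:
                sol = least_squares(residual, np.log([tr0, to0]), diff_step=1e-4)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("tuning-model fit did not converge")
    tr, tosc = np.exp(best.x)
    theta = FlashTemplateParams(1.0, tr, tr, tosc, -np.pi / 4)
    _, dense_curve = _model_curve(theta, freqs, dense, spectrum)
    fit = TuningFit(
        theta=theta,
        cutoff_10pct=np.nan,
        loss_value=float(2 * best.cost),
        dense_freqs=dense,
        dense_curve=dense_curve,
        spectrum_kind=spectrum,
    )
    fit.cutoff_10pct = cutoff_frequency(fit)
    fit.extrapolated = fit.cutoff_10pct > freqs.max()
    return fit


def cutoff_frequency(fit: TuningFit, fraction: float = 0.1) -> float:
    """Smallest frequency above the curve's peak where it falls to
    ``fraction`` of its maximum, by interpolation on the dense grid."""
    f, y = fit.dense_freqs, fit.dense_curve
    i_pk = int(np.argmax(y))
    target = fraction * y[i_pk]
    below = np.flatnonzero(y[i_pk:] <= target)
    if below.size == 0:
        raise ValueError(
            f"fitted curve never reaches {fraction:g} of maximum within "
            f"[{f[0]:g}, {f[-1]:g}] Hz"
        )
    j = i_pk + below[0]
    if j == i_pk:
        return float(f[j])
    # log-linear interpolation between the bracketing grid points
    y0, y1 = np.log(y[j - 1]), np.log(y[j])
    return float(f[j - 1] + (np.log(target) - y0) / (y1 - y0) * (f[j] - f[j - 1]))
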