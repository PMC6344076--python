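"""Linear-filter estimation and linear-nonlinear (LN) model construction.

A cell's linear filter is the kernel whose convolution with a Gaussian-noise
stimulus best predicts the response (reverse correlation).  Because the
stimulus is band-limited (0-60 Hz), the estimator divides the average
cross-spectrum by the average stimulus power spectrum with a regularisation
floor, which removes the bias the stimulus autocorrelation would otherwise
introduce.  For spiking cells the same estimator is applied to the binary
spike vector, and a static nonlinearity (a scaled Gaussian CDF) maps the
generator signal — the stimulus convolved with the filter — to spike
probability per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit
from scipy.stats import norm

from .recording import Recording, SpikeTrain
from .template import FlashTemplateParams, evaluate_template

logger = logging.getLogger(__name__)

__all__ = [
    "LinearFilter",
    "NonlinearityParams",
    "estimate_filter",
    "generator_signal",
    "estimate_nonlinearity",
    "detect_spikes",
    "filter_shift",
]


@dataclass
class LinearFilter:
    """Discrete causal filter kernel.

    ``weights`` is the discrete-convolution kernel: response[n] =
    sum_k weights[k] * stimulus[n-k].  Read as a continuous kernel the
    impulse response is weights * sampling_rate.
    """

    weights: np.ndarray
    sampling_rate: float
    regularization: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(len(self.weights)) / self.sampling_rate * 1e3

    @property
    def peak_lag_ms(self) -> float:
        """Lag of the dominant extremum (sample grid)."""
        return float(np.argmax(np.abs(self.weights)) / self.sampling_rate * 1e3)

    @classmethod
    def from_template(
        cls,
        params: FlashTemplateParams,
        sampling_rate: float,
        duration_ms: float = 500.0,
        gain: float = 1.0,
        sign: float = 1.0,
    ) -> "LinearFilter":
        """Sample a flash-template-shaped kernel.

        ``gain`` is the DC... peak gain of the continuous kernel in response
        units per stimulus unit per second; weights include the 1/fs factor
        so discrete convolution approximates the continuous integral.
        """
        t = np.arange(0.0, duration_ms, 1e3 / sampling_rate)
        h = sign * gain * evaluate_template(params, t)
        return cls(weights=h / sampling_rate, sampling_rate=sampling_rate)


@dataclass
class NonlinearityParams:
    """Static spiking nonlinearity: p(g) = max_rate * Phi((g - center)/spread)."""

    max_rate: float
    center: float
    spread: float
    bin_centers: np.ndarray | None = None
    bin_probabilities: np.ndarray | None = None
    flat: bool = False

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    def __call__(self, g: np.ndarray) -> np.ndarray:
        p = self.max_rate * norm.cdf((np.asarray(g) - self.center) / self.spread)
        return np.clip(p, 0.0, 1.0)


def _segmented_spectra(x: np.ndarray, y: np.ndarray, nperseg: int):
    """Average cross- and auto-spectra over half-overlapping Hann segments."""
    n = len(x)
    step = nperseg // 2
    win = np.hanning(nperseg)
    cross = np.zeros(nperseg // 2 + 1, dtype=complex)
    auto = np.zeros(nperseg // 2 + 1)
    count = 0
    for start in range(0, n - nperseg + 1, step):
        xs = np.fft.rfft(win * x[start : start + nperseg])
        ys = np.fft.rfft(win * y[start : start + nperseg])
        cross += np.conj(xs) * ys
        auto += np.abs(xs) ** 2
        count += 1
    if count == 0:
        raise ValueError("trace shorter than one spectral segment")
    return cross / count, auto / count


def estimate_filter(
    stimulus: np.ndarray,
    response: np.ndarray,
    sampling_rate: float,
    max_lag_ms: float = 500.0,
    regularization: float = 0.01,
    segment_s: float = 1.0,
) -> LinearFilter:
    """Reverse-correlation filter by regularised spectral division.

    F(w) = <S*(w) R(w)> / (<|S(w)|^2> + floor), with the floor set to
    ``regularization`` times the peak stimulus power; averaged over
    half-overlapping Hann segments of ``segment_s`` seconds, then inverse
    transformed and truncated to ``max_lag_ms``.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    response = np.asarray(response, dtype=float)
    if stimulus.shape != response.shape:
        raise ValueError("stimulus and response must have equal length")
    if stimulus.std() == 0:
        raise ValueError("stimulus has zero variance")
    x = stimulus - stimulus.mean()
    y = response - response.mean()
    nperseg = min(int(round(segment_s * sampling_rate)), len(x))
    cross, auto = _segmented_spectra(x, y, nperseg)
    floor = regularization * auto.max()
    transfer = cross / (auto + floor)
    kernel = np.fft.irfft(transfer, n=nperseg)
    n_lag = min(int(round(max_lag_ms * 1e-3 * sampling_rate)), len(kernel))
    return LinearFilter(
        weights=kernel[:n_lag], sampling_rate=sampling_rate, regularization=regularization
    )


def generator_signal(stimulus: np.ndarray, filt: LinearFilter) -> np.ndarray:
    """Causal convolution of the stimulus with the filter kernel."""
    stimulus = np.asarray(stimulus, dtype=float)
    full = signal.fftconvolve(stimulus, filt.weights, mode="full")
    return full[: len(stimulus)]


def estimate_nonlinearity(
    gen: np.ndarray,
    spikes: SpikeTrain | np.ndarray,
    n_bins: int = 20,
    flat_threshold: float = 10.0,
) -> NonlinearityParams:
    """Binned spike probability vs generator signal, fit with a Gaussian CDF.

    Bins are equal-occupancy (quantiles of the generator signal).  A fitted
    spread exceeding ``flat_threshold`` times the generator SD flags the
    curve as flat (no resolvable threshold).
    """
    gen = np.asarray(gen, dtype=float)
    if isinstance(spikes, SpikeTrain):
        vec = spikes.to_binary(len(gen) * spikes.bin_width)
    else:
        vec = spikes
    vec = np.asarray(vec, dtype=float)
    if len(vec) != len(gen):
        raise ValueError("generator signal and spike vector must be aligned")
    if vec.sum() == 0:
        raise ValueError("no spikes: nonlinearity fit is degenerate")
    edges = np.quantile(gen, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, gen, side="right") - 1, 0, n_bins - 1)
    centers = np.array([gen[idx == b].mean() for b in range(n_bins)])
    probs = np.array([vec[idx == b].mean() for b in range(n_bins)])
    counts = np.array([(idx == b).sum() for b in range(n_bins)])

    def model(g, pmax, c, s):
        return pmax * norm.cdf((g - c) / s)

    g_sd = gen.std() or 1.0
    sigma = np.sqrt(np.maximum(probs * (1 - probs), 1e-4) / np.maximum(counts, 1))
    try:
        popt, _ = curve_fit(
            model,
            centers,
            probs,
            p0=[min(1.0, 2 * probs.max()), centers[np.argmin(np.abs(probs - probs.max() / 2))], g_sd],
            sigma=sigma,
            bounds=([1e-6, centers.min() - 10 * g_sd, 1e-9], [1.0, centers.max() + 10 * g_sd, 1e3 * g_sd]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"nonlinearity fit did not converge: {err}") from err
    pmax, c, s = popt
    flat = s > flat_threshold * g_sd
    if flat:
        logger.warning("nonlinearity is flat (spread %.3g >> generator SD %.3g)", s, g_sd)
    return NonlinearityParams(pmax, c, s, centers, probs, flat=flat)


def detect_spikes(
    trace: Recording | np.ndarray,
    sampling_rate: float | None = None,
    threshold_sd: float = 5.0,
    refractory_ms: float = 2.0,
    highpass_hz: float = 300.0,
) -> SpikeTrain:
    """Threshold-crossing spike detection on a high-pass-filtered trace.

    The threshold is ``threshold_sd`` times the robust (median absolute
    deviation) SD; polarity is chosen from the larger extreme; refractory
    violations keep the earlier event.
    """
    if isinstance(trace, Recording):
        x, fs = trace.samples, trace.sampling_rate
    else:
        x, fs = np.asarray(trace, dtype=float), sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for array input")
    sos = signal.butter(3, highpass_hz, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, x)
    robust_sd = np.median(np.abs(hp - np.median(hp))) / 0.6745
    if robust_sd == 0:
        return SpikeTrain(times=np.array([]), bin_width=1.0 / fs, duration=len(x) / fs)
    if abs(hp.min()) >= abs(hp.max()):
        hp = -hp
    thresh = threshold_sd * robust_sd
    above = hp > thresh
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    # crossing runs closer than the refractory period merge into one event;
    # the event time is the extremum over the merged span
    refr_samples = int(round(refractory_ms * 1e-3 * fs))
    times = []
    i = 0
    while i < len(onsets):
        start = onsets[i]
        end = start
        while end < len(hp) and above[end]:
            end += 1
        j = i + 1
        while j < len(onsets) and onsets[j] - onsets[j - 1] < refr_samples:
            end = onsets[j]
            while end < len(hp) and above[end]:
                end += 1
            j += 1
        times.append((start + int(np.argmax(hp[start:end]))) / fs)
        i = j
    return SpikeTrain(times=np.array(times), bin_width=1.0 / fs, duration=len(x) / fs)


def filter_shift(
    filter_low: LinearFilter,
    filter_high: LinearFilter,
    method: str = "template_fit",
) -> float:
    """Peak-time shift (ms) between filters at low and high background.

    Returns time_to_peak(low) - time_to_peak(high); positive values mean the
    response speeds up with background.  Peak times come from flash-template
    fits to the polarity-rectified filters (or the chosen kinetics method).
    """
    from .kinetics import time_to_peak

    if filter_low.sampling_rate != filter_high.sampling_rate:
        raise ValueError("filters must share a sampling rate")
    pol_low = np.sign(filter_low.weights[np.argmax(np.abs(filter_low.weights))])
    pol_high = np.sign(filter_high.weights[np.argmax(np.abs(filter_high.weights))])
    if pol_low != pol_high:
        logger.warning("filters at the two backgrounds have opposite polarities")
    t_low = time_to_peak(filter_low, method=method)
    t_high = time_to_peak(filter_high, method=method)
    return float(t_low - t_high)
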