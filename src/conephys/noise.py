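"""Noise spectral analysis, band powers, and detection thresholds.

Current fluctuations in a voltage-clamp recording combine cellular noise
(phototransduction) and instrumental noise.  A near-saturating light shuts
phototransduction down, so the spectrum recorded in saturating light is the
instrumental component alone; assuming independence, cellular noise at any
background is the spectral difference.  Band powers integrate the two-sided
density over a frequency range (flash-response band 2-16 Hz, high-frequency
band 20-394 Hz by default) with the ±frequency symmetry factor, and are
reported normalised to their value in darkness.

Detection thresholds convert noise into an equivalent flash strength: the
number of isomerizations whose response matches the noise power in a 200 ms
integration window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording
from .template import FlashTemplateParams, template_power_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PSDEstimate",
    "BandDefinition",
    "NoiseSummary",
    "DEFAULT_BANDS",
    "compute_psd",
    "isolate_cellular_noise",
    "band_power",
    "noise_vs_background",
    "flash_response_psd",
    "detection_threshold",
    "noise_effective_isomerizations",
]


@dataclass
class PSDEstimate:
    """Two-sided power spectral density on a nonnegative frequency grid.

    ``density`` holds the two-sided convention (pA²/Hz): the full variance
    is the integral over ± frequencies, i.e. twice the integral over the
    positive grid (plus the DC bin).
    """

    frequencies: np.ndarray
    density: np.ndarray
    n_segments: int = 1
    segment_length: float = 0.0
    units: str = "pA^2/Hz"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies.shape != self.density.shape:
            raise ValueError("frequency and density grids must match")

    def total_power(self) -> float:
        """Variance implied by the estimate (Parseval)."""
        return float(2.0 * np.trapezoid(self.density, self.frequencies))


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lower edge must be below upper edge")


DEFAULT_BANDS = (
    BandDefinition("flash_response", 2.0, 16.0),
    BandDefinition("high_frequency", 20.0, 394.0),
)


@dataclass
class NoiseSummary:
    """Per-background cellular band powers, normalised to darkness."""

    backgrounds: np.ndarray
    band_powers: dict  # band name -> array of pA² per background
    normalized_powers: dict  # band name -> array, darkness entry == 1
    detection_threshold: float | None = None
    noise_effective_isomerizations: float | None = None
    meta: dict = field(default_factory=dict)


def compute_psd(trace, sampling_rate: float | None = None,
                segment_length: float = 1.0) -> PSDEstimate:
    """Segment-averaged (Welch) two-sided PSD: Hann window, 50% overlap."""
    if isinstance(trace, Recording):
        x, fs = trace.samples, trace.sampling_rate
        if x.ndim == 2:
            x = x.reshape(-1)
    else:
        x, fs = np.asarray(trace, dtype=float), sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for array input")
    nperseg = int(round(segment_length * fs))
    if len(x) < nperseg:
        raise ValueError("trace shorter than one spectral segment")
    if len(x) < 2 * nperseg:
        raise ValueError("trace must cover at least two spectral segments")
    freqs, p1 = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", return_onesided=True, scaling="density",
    )
    # one-sided -> two-sided: interior bins carry half the one-sided density
    p2 = p1.copy()
    if len(p2) > 2:
        p2[1:-1] /= 2.0
    if nperseg % 2 != 0 and len(p2) > 1:
        p2[-1] /= 2.0  # odd segment: last bin is not Nyquist
    n_segments = 1 + (len(x) - nperseg) // (nperseg // 2)
    return PSDEstimate(freqs, p2, n_segments=n_segments,
                       segment_length=segment_length)


def isolate_cellular_noise(psd_condition: PSDEstimate,
                           psd_saturating: PSDEstimate) -> PSDEstimate:
    """Cellular noise spectrum: condition minus saturating (instrumental).

    The difference may be negative in individual bins; negativity is logged
    but retained so band powers stay unbiased.
    """
    if not np.array_equal(psd_condition.frequencies, psd_saturating.frequencies):
        raise ValueError("PSD frequency grids do not match")
    diff = psd_condition.density - psd_saturating.density
    frac_neg = float(np.mean(diff < 0))
    if frac_neg > 0:
        logger.info("isolated spectrum negative in %.1f%% of bins", 100 * frac_neg)
    return PSDEstimate(psd_condition.frequencies.copy(), diff,
                       n_segments=min(psd_condition.n_segments, psd_saturating.n_segments),
                       segment_length=psd_condition.segment_length)


def band_power(psd: PSDEstimate, band: BandDefinition) -> float:
    """Variance in a band: 2 x trapezoidal integral of the two-sided density.

    The factor 2 accounts for the symmetric negative-frequency half, so the
    result is a physical variance (pA²).
    """
    f = psd.frequencies
    if band.hi > f[-1] or band.lo < f[0]:
        raise ValueError(f"band [{band.lo}, {band.hi}] Hz outside the PSD grid "
                         f"[{f[0]}, {f[-1]}] Hz")
    inside = (f > band.lo) & (f < band.hi)
    grid = np.concatenate(([band.lo], f[inside], [band.hi]))
    vals = np.concatenate((
        [np.interp(band.lo, f, psd.density)],
        psd.density[inside],
        [np.interp(band.hi, f, psd.density)],
    ))
    return float(2.0 * np.trapezoid(vals, grid))


def noise_vs_background(
    recordings: dict,
    bands: tuple = DEFAULT_BANDS,
    segment_length: float = 1.0,
) -> NoiseSummary:
    """Full noise pipeline for one cell across backgrounds.

    ``recordings`` maps condition keys to Recordings: the float background
    rate (R*/s, 0.0 meaning darkness) for each measured background, plus the
    string key 'saturating'.  For each background the cellular spectrum is
    isolated by subtracting the saturating-light spectrum, integrated per
    band, and normalised by the darkness band power.
    """
    if "saturating" not in recordings:
        raise ValueError("a 'saturating' recording is required to isolate cellular noise")
    bg_keys = sorted(k for k in recordings if not isinstance(k, str))
    if 0.0 not in bg_keys:
        raise ValueError("a darkness (background 0.0) recording is required")
    psd_sat = compute_psd(recordings["saturating"], segment_length=segment_length)
    backgrounds = np.array(bg_keys, dtype=float)
    powers = {b.name: np.empty(len(bg_keys)) for b in bands}
    for i, bg in enumerate(bg_keys):
        cellular = isolate_cellular_noise(
            compute_psd(recordings[bg], segment_length=segment_length), psd_sat
        )
        for b in bands:
            powers[b.name][i] = band_power(cellular, b)
    i_dark = bg_keys.index(0.0)
    normalized = {}
    for b in bands:
        dark = powers[b.name][i_dark]
        if dark <= 0:
            raise ValueError(f"darkness band power nonpositive in band {b.name!r}")
        normalized[b.name] = powers[b.name] / dark
    return NoiseSummary(backgrounds=backgrounds, band_powers=powers,
                        normalized_powers=normalized)


def flash_response_psd(
    params: FlashTemplateParams,
    freqs: np.ndarray | None = None,
    f_max: float = 400.0,
    df: float = 0.5,
) -> PSDEstimate:
    """Two-sided spectrum |H(f)|² of the continuous flash-template fit.

    For the deterministic template this is an energy spectrum (pA²·s²·...);
    it is used for band-power ratios against noise, where only relative
    magnitudes matter.
    """
    f = np.arange(0.0, f_max + df / 2, df) if freqs is None else np.asarray(freqs, float)
    dens = template_power_spectrum(params, f)
    return PSDEstimate(f, dens, units="(response units x s)^2")


def _window_noise_power(noise: Recording, window_s: float, lowpass_hz: float = 3000.0) -> float:
    """Mean within-window variance over non-overlapping windows."""
    x, fs = noise.samples, noise.sampling_rate
    if x.ndim == 2:
        x = x.reshape(-1)
    if lowpass_hz < fs / 2:
        sos = signal.butter(3, lowpass_hz, btype="lowpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    w = int(round(window_s * fs))
    if w > len(x):
        raise ValueError("integration window longer than the noise recording")
    n_win = len(x) // w
    segs = x[: n_win * w].reshape(n_win, w)
    return float(np.mean(segs.var(axis=1)))


def detection_threshold(
    single_photon_response: Recording | np.ndarray,
    cellular_noise: Recording,
    window_s: float = 0.2,
    sampling_rate: float | None = None,
) -> float:
    """Flash strength (R*) whose response power matches the windowed noise power.

    The response power of a flash of strength q is q² times the mean squared
    single-photon response over the integration window, so the threshold is
    the square root of the noise-to-response power ratio — linear in the
    noise SD.
    """
    if isinstance(single_photon_response, Recording):
        spr, fs = single_photon_response.samples, single_photon_response.sampling_rate
    else:
        spr, fs = np.asarray(single_photon_response, float), sampling_rate
        if fs is None:
            raise ValueError("sampling_rate required for array input")
    w = int(round(window_s * fs))
    p_resp = float(np.mean(spr[:w] ** 2))
    if p_resp == 0:
        raise ValueError("single-photon response has zero amplitude")
    p_noise = _window_noise_power(cellular_noise, window_s)
    return float(np.sqrt(p_noise / p_resp))


def noise_effective_isomerizations(
    flash_psd_per_rstar: PSDEstimate,
    cellular_psd: PSDEstimate,
    band: BandDefinition = DEFAULT_BANDS[0],
) -> float:
    """Flash strength (R*) whose response band power equals the noise band power."""
    p_noise = band_power(cellular_psd, band)
    if p_noise <= 0:
        raise ValueError("cellular band power must be positive")
    p_resp = band_power(flash_psd_per_rstar, band)
    if p_resp <= 0:
        raise ValueError("per-R* response band power must be positive")
    return float(np.sqrt(p_noise / p_resp))
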