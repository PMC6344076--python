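"""Cone spectral sensitivities and silent-substitution stimulus design.

Cone-isolating stimuli modulate three LEDs so that exactly one cone type sees
a change in photon-absorption rate.  The forward map from LED drives to
per-cone isomerization rates is a 3x3 matrix of overlap integrals between LED
emission spectra and cone spectral sensitivities (scaled by the cone's
effective collecting area, default 0.37 um^2); its inverse maps target
per-cone rates back to LED drives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "pigment_nomogram",
    "gaussian_led_spectrum",
    "led_spectrum_from_csv",
    "ConeIsolationMatrix",
    "isomerization_rate",
    "cone_isolating_stimulus",
]

DEFAULT_LAMBDA_MAX = {"S": 430.0, "M": 531.0, "L": 561.0}
DEFAULT_LED_PEAKS = (406.0, 515.0, 640.0)
DEFAULT_COLLECTING_AREA = 0.37  # um^2

_NOMOGRAM_RANGE = (330.0, 800.0)


def pigment_nomogram(lambda_max: float, wavelengths: np.ndarray) -> np.ndarray:
    """A1 visual-pigment absorbance template (Govardovskii-style).

    Returns relative spectral sensitivity normalised to exactly 1 at
    ``lambda_max``; includes the ultraviolet beta band.  Valid for
    lambda_max in [350, 650] nm and wavelengths within 330-800 nm.
    """
    if not (350.0 <= lambda_max <= 650.0):
        raise ValueError("lambda_max must lie in [350, 650] nm")
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(wl < _NOMOGRAM_RANGE[0]) or np.any(wl > _NOMOGRAM_RANGE[1]):
        raise ValueError(f"wavelength grid outside template validity {_NOMOGRAM_RANGE}")

    def _alpha_beta(lam: np.ndarray) -> np.ndarray:
        x = lambda_max / lam
        A, B, C, D = 69.7, 28.0, -14.9, 0.674
        a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
        b, c = 0.922, 1.104
        alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
        lam_b = 189.0 + 0.315 * lambda_max
        d_b = -40.5 + 0.195 * lambda_max
        beta = 0.26 * np.exp(-(((lam - lam_b) / d_b) ** 2))
        return alpha + beta

    peak = float(_alpha_beta(np.array([lambda_max]))[0])
    return _alpha_beta(wl) / peak


def gaussian_led_spectrum(
    peak_nm: float, wavelengths: np.ndarray, fwhm_nm: float = 25.0
) -> np.ndarray:
    """Gaussian LED emission profile (photon flux per nm per unit drive)."""
    wl = np.asarray(wavelengths, dtype=float)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((wl - peak_nm) ** 2) / (2.0 * sigma**2))


def led_spectrum_from_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a two-column (wavelength_nm, value) spectrum."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]


@dataclass
class ConeIsolationMatrix:
    """Forward/inverse maps between LED drives and per-cone R*/s.

    matrix[i, j] is the isomerization rate in cone type i per unit drive of
    LED j; rows are ordered (S, M, L) and columns follow ``led_peaks``.
    """

    wavelengths: np.ndarray
    led_spectra: np.ndarray  # (3, n_wl) photon flux per unit drive
    cone_spectra: np.ndarray  # (3, n_wl) relative sensitivity, rows S/M/L
    collecting_area: float = DEFAULT_COLLECTING_AREA
    led_peaks: tuple = DEFAULT_LED_PEAKS
    matrix: np.ndarray = field(init=False)
    inverse: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        overlap = np.trapezoid(
            self.cone_spectra[:, None, :] * self.led_spectra[None, :, :], wl, axis=-1
        )
        self.matrix = self.collecting_area * overlap
        if np.any(self.matrix < 0):
            raise ValueError("isomerization matrix entries must be nonnegative")
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("cone isolation matrix is singular")
        self.inverse = np.linalg.inv(self.matrix)

    @classmethod
    def default(
        cls,
        led_peaks: tuple = DEFAULT_LED_PEAKS,
        led_fwhm_nm: float = 25.0,
        lambda_max: dict | None = None,
        collecting_area: float = DEFAULT_COLLECTING_AREA,
        wavelengths: np.ndarray | None = None,
    ) -> "ConeIsolationMatrix":
        lmax = dict(DEFAULT_LAMBDA_MAX, **(lambda_max or {}))
        wl = np.arange(350.0, 751.0) if wavelengths is None else np.asarray(wavelengths)
        leds = np.stack([gaussian_led_spectrum(p, wl, led_fwhm_nm) for p in led_peaks])
        cones = np.stack([pigment_nomogram(lmax[c], wl) for c in ("S", "M", "L")])
        return cls(wl, leds, cones, collecting_area, tuple(led_peaks))


def isomerization_rate(led_drives: np.ndarray, matrix: ConeIsolationMatrix) -> np.ndarray:
    """Per-cone isomerization rates (S, M, L order) for given LED drives.

    ``led_drives`` may be a length-3 vector or a (3, n_time) array.
    """
    drives = np.asarray(led_drives, dtype=float)
    if np.any(drives < 0):
        raise ValueError("LED drives must be nonnegative")
    return matrix.matrix @ drives


def cone_isolating_stimulus(
    target_contrast: np.ndarray,
    matrix: ConeIsolationMatrix,
    mean_drives: np.ndarray,
    modulation: np.ndarray | None = None,
    max_drive: float = np.inf,
) -> np.ndarray:
    """LED drive waveforms realising target per-cone contrasts.

    target_contrast : length-3 contrasts (S, M, L); zero entries are the
        "silent" cone types whose isomerization rate must not modulate.
    mean_drives : steady per-LED drives setting the adapting background.
    modulation : unit-amplitude temporal profile (default: a single +1/-1
        square alternation of length 2); the drive modulation is its outer
        product with the solved per-LED amplitudes.

    Returns a (3, n_time) array of drives.  Raises if any drive leaves
    [0, max_drive], naming the offending LED and sample.
    """
    target = np.asarray(target_contrast, dtype=float)
    mean_drives = np.asarray(mean_drives, dtype=float)
    if modulation is None:
        modulation = np.array([1.0, -1.0])
    mean_rates = matrix.matrix @ mean_drives
    delta_rates = target * mean_rates
    delta_drives = matrix.inverse @ delta_rates
    drives = mean_drives[:, None] + np.outer(delta_drives, modulation)
    bad = (drives < 0) | (drives > max_drive)
    if np.any(bad):
        led, t = np.argwhere(bad)[0]
        raise ValueError(
            f"LED {led} (peak {matrix.led_peaks[led]} nm) out of gamut at sample {t}: "
            f"drive {drives[led, t]:.4g} outside [0, {max_drive}]"
        )
    return drives
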