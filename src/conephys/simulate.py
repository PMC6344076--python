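"""Synthetic cone and ganglion-cell recordings with known ground truth.

The generative model mirrors what the analyses assume: flash responses are a
scaled flash template plus additive coloured noise; continuous noise is the
sum of an instrumental component (present even when phototransduction is
saturated), a background-independent cellular component, and — on a
background — a Poisson photon-absorption component whose power spectrum is
the absorption rate times the squared transfer function of the single-photon
response (Campbell's theorem).  Noise is synthesised by frequency-domain
shaping of white Gaussian noise, which has exactly the target spectrum in
expectation.  Spiking cells are simulated as an LN cascade with per-bin
Bernoulli spike draws.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .ln import LinearFilter, NonlinearityParams
from .recording import Recording, SpikeTrain
from .template import FlashTemplateParams, evaluate_template, template_transfer

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseSpec",
    "ConeSimSpec",
    "colored_noise",
    "simulate_flash_trials",
    "simulate_noise_recording",
    "simulate_gaussian_noise_response",
    "simulate_sbc_spikes",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Parametric noise power spectra (two-sided, pA²/Hz or mV²/Hz).

    instrumental: first-order spectrum level/(1+(f/corner)²) — flat at low
    frequencies, rolling off at the acquisition filter corner.
    cellular: sum of Lorentzians scale/(1+(f/corner)²); scales are the
    zero-frequency two-sided densities.
    include_poisson_component: add background x |H_single_photon(f)|² when the
    simulated condition has a background.
    """

    instrumental_level: float = 1e-4
    instrumental_corner: float = 3000.0
    cellular_scales: tuple = (2e-3,)
    cellular_corners: tuple = (20.0,)
    include_poisson_component: bool = True

    def __post_init__(self) -> None:
        if self.instrumental_level < 0 or any(s < 0 for s in self.cellular_scales):
            raise ValueError("spectral densities must be nonnegative")
        if len(self.cellular_scales) != len(self.cellular_corners):
            raise ValueError("cellular scales and corners must pair up")

    def instrumental_psd(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        return self.instrumental_level / (1.0 + (f / self.instrumental_corner) ** 2)

    def cellular_psd(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        out = np.zeros_like(f)
        for s, c in zip(self.cellular_scales, self.cellular_corners):
            out += s / (1.0 + (f / c) ** 2)
        return out


@dataclass(frozen=True)
class ConeSimSpec:
    """Ground-truth description of one simulated cone.

    template: unit-peak flash waveform shape (per-R* response is
    single_photon_amplitude x template).
    single_photon_amplitude: response to one isomerization, pA or mV.
    background: steady absorption rate, R*/s.
    """

    cone_type: str
    background: float
    template: FlashTemplateParams
    single_photon_amplitude: float = 0.03
    noise_model: NoiseSpec = field(default_factory=NoiseSpec)
    sampling_rate: float = 10_000.0
    seed: int = 0
    modality: str = "current"
    cell_id: str = ""
    retina_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.background < 0:
            raise ValueError("background must be nonnegative")
        if self.single_photon_amplitude <= 0:
            raise ValueError("single_photon_amplitude must be positive")

    def single_photon_transfer(self, freqs: np.ndarray) -> np.ndarray:
        """|H(f)| of the single-photon response, response-units x s."""
        return self.single_photon_amplitude * np.abs(template_transfer(self.template, freqs))

    def poisson_psd(self, freqs: np.ndarray) -> np.ndarray:
        """Two-sided shot-noise PSD: rate x |H(f)|²; zero in darkness."""
        if self.background == 0 or not self.noise_model.include_poisson_component:
            return np.zeros_like(np.asarray(freqs, dtype=float))
        return self.background * self.single_photon_transfer(freqs) ** 2

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of this spec's seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


def colored_noise(
    psd_func, n: int, sampling_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a target two-sided PSD via frequency-domain shaping.

    ``psd_func(freqs_hz)`` must return the two-sided density at nonnegative
    frequencies; the realised trace has that spectrum in expectation and
    variance equal to its integral over ±frequencies.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    p2 = np.asarray(psd_func(freqs), dtype=float)
    if np.any(p2 < 0):
        raise ValueError("target PSD must be nonnegative")
    # one-sided density: doubled except at DC (and Nyquist for even n)
    s1 = p2.copy()
    s1[1:] *= 2.0
    if n % 2 == 0:
        s1[-1] = p2[-1]
    z = np.empty(len(freqs), dtype=complex)
    amp_mid = np.sqrt(s1 * sampling_rate * n / 4.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    z = amp_mid * (re + 1j * im)
    z[0] = np.sqrt(s1[0] * sampling_rate * n / 2.0) * re[0]
    if n % 2 == 0:
        z[-1] = np.sqrt(s1[-1] * sampling_rate * n / 2.0) * re[-1]
    return np.fft.irfft(z, n=n)


def _flash_component(
    spec: ConeSimSpec, flash_strength: float, n: int, flash_time: float
) -> np.ndarray:
    t_ms = (np.arange(n) / spec.sampling_rate - flash_time) * 1e3
    return flash_strength * spec.single_photon_amplitude * evaluate_template(
        spec.template, t_ms
    )


def simulate_flash_trials(
    spec: ConeSimSpec,
    flash_strength: float,
    n_trials: int,
    trace_length: float = 0.5,
    flash_time: float = 0.05,
) -> Recording:
    """Trial block of flash responses: scaled template plus noise.

    Each trial is flash_strength x single_photon_amplitude x template
    (shifted to ``flash_time``) plus an independent noise realisation of the
    spec's instrumental+cellular(+Poisson) spectrum.  The flash response is
    linear in flash strength by construction.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n = int(round(trace_length * spec.sampling_rate))
    peak_ms = flash_time * 1e3 + 2 * spec.template.t_decay + spec.template.t_rise
    if peak_ms > trace_length * 1e3:
        raise ValueError("flash_time + template support must fit in trace_length")
    mean_trace = _flash_component(spec, flash_strength, n, flash_time)

    def psd(freqs):
        return (
            spec.noise_model.instrumental_psd(freqs)
            + spec.noise_model.cellular_psd(freqs)
            + spec.poisson_psd(freqs)
        )

    trials = np.empty((n_trials, n))
    for i in range(n_trials):
        trials[i] = mean_trace + colored_noise(psd, n, spec.sampling_rate, spec.rng(1, i))
    return Recording(
        samples=trials,
        sampling_rate=spec.sampling_rate,
        modality=spec.modality,
        background=spec.background,
        cone_type=spec.cone_type,
        cell_id=spec.cell_id,
        retina_id=spec.retina_id,
        units="pA" if spec.modality == "current" else "mV",
        meta={"flash_strength": flash_strength, "flash_time": flash_time},
    )


NOISE_CONDITIONS = ("background", "saturating", "darkness")


def simulate_noise_recording(
    spec: ConeSimSpec, duration: float, condition: str = "background"
) -> Recording:
    """Continuous noise trace for one recording condition.

    saturating: instrumental noise only (phototransduction shut down);
    darkness: instrumental + cellular;
    background: instrumental + cellular + Poisson photon noise at the spec's
    background rate.
    """
    if condition not in NOISE_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    n = int(round(duration * spec.sampling_rate))

    def psd(freqs):
        total = spec.noise_model.instrumental_psd(freqs)
        if condition in ("darkness", "background"):
            total = total + spec.noise_model.cellular_psd(freqs)
        if condition == "background":
            total = total + spec.poisson_psd(freqs)
        return total

    samples = colored_noise(psd, n, spec.sampling_rate, spec.rng(2))
    return Recording(
        samples=samples,
        sampling_rate=spec.sampling_rate,
        modality=spec.modality,
        background=spec.background if condition == "background" else 0.0,
        cone_type=spec.cone_type,
        cell_id=spec.cell_id,
        retina_id=spec.retina_id,
        meta={"condition": condition},
    )


def simulate_gaussian_noise_response(
    filt: LinearFilter,
    stimulus: np.ndarray,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    sampling_rate: float | None = None,
    noise_sd: float | None = None,
) -> Recording:
    """Photocurrent response to a Gaussian-noise stimulus: stim ⊛ filter + noise.

    ``noise_sd``, if given, rescales the additive noise realisation to that
    SD (convenient for setting a signal-to-noise ratio directly).
    """
    stimulus = np.asarray(stimulus, dtype=float)
    fs = filt.sampling_rate
    if sampling_rate is not None and sampling_rate != fs:
        raise ValueError("stimulus sampling rate must match the filter's")
    clean = _signal.fftconvolve(stimulus - stimulus.mean(), filt.weights, mode="full")[
        : len(stimulus)
    ]
    out = clean
    if noise is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        nz = colored_noise(
            lambda f: noise.instrumental_psd(f) + noise.cellular_psd(f),
            len(stimulus),
            fs,
            rng,
        )
        if noise_sd is not None and nz.std() > 0:
            nz = nz * (noise_sd / nz.std())
        out = clean + nz
    return Recording(samples=out, sampling_rate=fs, modality="current",
                     meta={"clean_sd": float(clean.std())})


def simulate_sbc_spikes(
    s_filter: LinearFilter,
    lm_filter: LinearFilter,
    nonlinearity: NonlinearityParams,
    stimulus: np.ndarray,
    channel: str = "s",
    seed: int = 0,
) -> SpikeTrain:
    """LN-cascade spike train of a small bistratified cell.

    Exactly one filter applies per cone-isolating channel: the positive-going
    S filter for an S-cone-isolating stimulus, the negative-going LM filter
    for an LM-isolating one.  Spikes are per-bin Bernoulli draws with
    probability nonlinearity(generator signal), clipped to [0, 1].
    """
    if channel not in ("s", "lm"):
        raise ValueError("channel must be 's' or 'lm'")
    filt = s_filter if channel == "s" else lm_filter
    if np.argmax(s_filter.weights) != np.argmax(np.abs(s_filter.weights)):
        logger.warning("S filter does not have a positive-going peak")
    if np.argmin(lm_filter.weights) != np.argmax(np.abs(lm_filter.weights)):
        logger.warning("LM filter does not have a negative-going peak")
    stimulus = np.asarray(stimulus, dtype=float)
    gen = _signal.fftconvolve(stimulus - stimulus.mean(), filt.weights, mode="full")[
        : len(stimulus)
    ]
    raw_p = nonlinearity.max_rate * _phi((gen - nonlinearity.center) / nonlinearity.spread)
    n_out = int(np.sum((raw_p < 0) | (raw_p > 1)))
    if n_out:
        logger.warning("%d spike probabilities clipped to [0, 1]", n_out)
    p = np.clip(raw_p, 0.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    vec = (rng.random(len(p)) < p).astype(float)
    return SpikeTrain.from_binary(vec, bin_width=1.0 / filt.sampling_rate)


def _phi(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.cdf(x)
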