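"""Calibrated synthetic cone/ganglion-cell ensembles.

These builders assemble populations of simulated cells whose ground truth is
taken from the calibration tables: per-cell kinetic parameters are drawn
around the calibrated group mean and recentred so the realised ensemble mean
equals the calibration target exactly (the ensembles exist to encode group
statistics, and recentring removes the sampling error a finite draw would
otherwise add to the encoded mean).  Noise levels follow the documented
conditions: flash trials at 10% of the peak amplitude, Gaussian-noise
responses at 25% of the response SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import calibration as calib
from .ln import LinearFilter, NonlinearityParams
from .recording import Recording, SpikeTrain
from .simulate import (
    ConeSimSpec,
    NoiseSpec,
    colored_noise,
    simulate_flash_trials,
    simulate_noise_recording,
    simulate_sbc_spikes,
)
from .stimuli import Stimulus, gaussian_noise_stimulus, sinusoid_stimulus
from .template import FlashTemplateParams, template_transfer

__all__ = [
    "jittered_scales",
    "scale_noise_to_sd",
    "noise_spec_sd",
    "flash_ensemble",
    "flash_ensemble_across_backgrounds",
    "tuning_ensemble",
    "calibrate_tuning_template",
    "filter_ensemble",
    "sbc_ensemble",
    "calibrate_single_photon_amplitude",
    "noise_ensemble",
    "DEFAULT_PROBE_FREQUENCIES",
    "DEFAULT_CONTRAST_RAMP",
]

DEFAULT_PROBE_FREQUENCIES = (1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0)
# contrast rises with frequency so high-frequency responses stay measurable
DEFAULT_CONTRAST_RAMP = (0.1, 0.15, 0.25, 0.4, 0.6, 0.8, 1.0)


def jittered_scales(
    n: int, sd_frac: float, rng: np.random.Generator, recenter: bool = True
) -> np.ndarray:
    """Multiplicative per-cell scale factors ~ N(1, sd_frac), mean exactly 1."""
    k = 1.0 + sd_frac * rng.standard_normal(n)
    k = np.clip(k, 0.3, 3.0)
    if recenter and n > 1:
        k = k / k.mean()
    return k


def noise_spec_sd(spec: NoiseSpec, sampling_rate: float) -> float:
    """Trace SD implied by a NoiseSpec (integral of the two-sided PSD)."""
    f = np.linspace(0.0, sampling_rate / 2, 20001)
    total = spec.instrumental_psd(f) + spec.cellular_psd(f)
    return float(np.sqrt(2.0 * np.trapezoid(total, f)))


def scale_noise_to_sd(spec: NoiseSpec, target_sd: float, sampling_rate: float) -> NoiseSpec:
    """Rescale both noise components so the trace SD equals ``target_sd``."""
    current = noise_spec_sd(spec, sampling_rate)
    if current == 0:
        raise ValueError("noise spec has zero power; cannot rescale")
    r = (target_sd / current) ** 2
    return NoiseSpec(
        instrumental_level=spec.instrumental_level * r,
        instrumental_corner=spec.instrumental_corner,
        cellular_scales=tuple(s * r for s in spec.cellular_scales),
        cellular_corners=spec.cellular_corners,
        include_poisson_component=spec.include_poisson_component,
    )


def flash_ensemble(
    cone_type: str,
    background: float,
    n_cells: int,
    n_trials: int = 10,
    seed: int = 0,
    cell_ttp_sd_ms: float = 5.0,
    trial_noise_frac: float = 0.10,
    peak_amplitude: float = 10.0,
    sampling_rate: float = 10_000.0,
    flash_time: float = 0.05,
    trace_length: float = 0.5,
) -> list[Recording]:
    """Population of flash-response trial blocks for one background.

    Each cell's template is the calibrated one for (cone_type, background),
    time-scaled by a recentred per-cell factor so that the ensemble mean time
    to peak (and FWHM) equals the calibration target; trial noise has SD
    ``trial_noise_frac`` times the response peak.
    """
    base = calib.template_for(cone_type, background)
    tgt = calib.CONE_FLASH_KINETICS[(cone_type, float(background))]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    scales = jittered_scales(n_cells, cell_ttp_sd_ms / tgt.time_to_peak, rng)
    # trial noise is specified directly as a fraction of the response peak,
    # so the Poisson decomposition is left out of the flash condition
    noise = scale_noise_to_sd(
        NoiseSpec(include_poisson_component=False),
        trial_noise_frac * peak_amplitude, sampling_rate,
    )
    spa = 0.03
    flash_strength = peak_amplitude / spa
    out = []
    for i, k in enumerate(scales):
        spec = ConeSimSpec(
            cone_type=cone_type,
            background=background,
            template=base.time_scaled(k),
            single_photon_amplitude=spa,
            noise_model=noise,
            sampling_rate=sampling_rate,
            seed=int(rng.integers(2**31)),
            modality="voltage",
            cell_id=f"{cone_type}{i:03d}",
        )
        rec = simulate_flash_trials(spec, flash_strength, n_trials, trace_length, flash_time)
        rec.meta["true_time_to_peak_ms"] = tgt.time_to_peak * k
        out.append(rec)
    return out


def flash_ensemble_across_backgrounds(
    cone_type: str,
    backgrounds: tuple = (1000.0, 5000.0, 10000.0, 50000.0),
    n_cells: int = 36,
    n_trials: int = 10,
    seed: int = 0,
    cell_ttp_sd_ms: float = 5.0,
    **kwargs,
) -> list[dict]:
    """Per-cell flash recordings across backgrounds with shared cell identity.

    Each cell keeps one kinetic scale factor across backgrounds, so relative
    times to peak reflect the calibrated background dependence, not cell
    resampling.  Returns one {background: Recording} dict per cell.
    """
    ref = calib.CONE_FLASH_KINETICS[(cone_type, 5000.0)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    scales = jittered_scales(n_cells, cell_ttp_sd_ms / ref.time_to_peak, rng)
    peak_amplitude = kwargs.pop("peak_amplitude", 10.0)
    trial_noise_frac = kwargs.pop("trial_noise_frac", 0.10)
    sampling_rate = kwargs.pop("sampling_rate", 10_000.0)
    noise = scale_noise_to_sd(
        NoiseSpec(include_poisson_component=False),
        trial_noise_frac * peak_amplitude, sampling_rate,
    )
    spa = 0.03
    cells = []
    for i, k in enumerate(scales):
        per_bg = {}
        for bg in backgrounds:
            base = calib.template_for(cone_type, bg)
            spec = ConeSimSpec(
                cone_type=cone_type,
                background=bg,
                template=base.time_scaled(k),
                single_photon_amplitude=spa,
                noise_model=noise,
                sampling_rate=sampling_rate,
                seed=int(rng.integers(2**31)),
                modality="voltage",
                cell_id=f"{cone_type}{i:03d}",
            )
            per_bg[bg] = simulate_flash_trials(
                spec, peak_amplitude / spa, n_trials, 0.5, 0.05
            )
        cells.append(per_bg)
    return cells


def calibrate_tuning_template(
    cone_type: str, background: float, spectrum: str = "power"
) -> FlashTemplateParams:
    """Template whose noiseless tuning-pipeline cutoff equals the calibrated one.

    Starts from the flash template for the cone type/background and solves
    for the time scale at which the full fit (template power spectrum fitted
    to the noiseless amplitude curve at the probe frequencies) returns the
    calibrated 10%-cutoff frequency.
    """
    from .tuning import TuningCurve, fit_tuning_model

    target, _sem, _n = calib.TUNING_CUTOFFS[(cone_type, float(background))]
    base = calib.template_for(cone_type, background)
    freqs = np.array(DEFAULT_PROBE_FREQUENCIES)

    def pipeline_cutoff(k: float) -> float:
        p = base.time_scaled(k)
        amps = np.abs(template_transfer(p, freqs, dt_ms=0.1))
        curve = TuningCurve(freqs, amps / amps.max())
        return fit_tuning_model(curve, spectrum=spectrum).cutoff_10pct

    def objective(logk: float) -> float:
        return pipeline_cutoff(np.exp(logk)) - target

    logk = brentq(objective, np.log(0.3), np.log(3.0), xtol=1e-4)
    return base.time_scaled(float(np.exp(logk)))


def tuning_ensemble(
    cone_type: str,
    background: float,
    n_cells: int = 15,
    seed: int = 0,
    frequencies: tuple = DEFAULT_PROBE_FREQUENCIES,
    contrasts: tuple = DEFAULT_CONTRAST_RAMP,
    duration: float = 4.0,
    sampling_rate: float = 2_000.0,
    cell_scale_sd: float = 0.05,
    response_noise_frac: float = 0.1,
) -> list[dict]:
    """Sinusoid responses per cell per frequency through calibrated filters.

    Each cell is an LTI system whose kernel is the tuning-calibrated
    template, time-scaled by a recentred per-cell factor; responses carry
    additive white noise at ``response_noise_frac`` of the response SD.
    Returns per cell a dict {frequency: (Recording, contrast)}.
    """
    base = calibrate_tuning_template(cone_type, background)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    scales = jittered_scales(n_cells, cell_scale_sd, rng)
    cells = []
    for i, k in enumerate(scales):
        filt = LinearFilter.from_template(
            base.time_scaled(k), sampling_rate, duration_ms=500.0, gain=1.0
        )
        per_f = {}
        for f, c in zip(frequencies, contrasts):
            stim = sinusoid_stimulus(
                Stimulus(kind="sinusoid", mean_level=background, duration=duration,
                         sampling_rate=sampling_rate, contrast=c, frequency=f)
            )
            from scipy.signal import fftconvolve

            resp = fftconvolve(stim - stim.mean(), filt.weights, mode="full")[: len(stim)]
            noise_sd = response_noise_frac * resp.std()
            resp = resp + noise_sd * rng.standard_normal(len(resp))
            per_f[f] = (
                Recording(samples=resp, sampling_rate=sampling_rate, modality="voltage",
                          background=background, cone_type=cone_type,
                          cell_id=f"{cone_type}t{i:03d}"),
                c,
            )
        cells.append(per_f)
    return cells


def filter_ensemble(
    cone_type: str = "S",
    background: float = 2500.0,
    n_cells: int = 12,
    seed: int = 0,
    duration: float = 60.0,
    sampling_rate: float = 10_000.0,
    cell_ttp_sd_ms: float = 3.0,
    noise_frac: float = 0.25,
    contrast: float = 0.5,
    bandwidth: float = 60.0,
) -> list[dict]:
    """Voltage-clamp Gaussian-noise runs through calibrated linear filters.

    Ground-truth kernels share the flash-template family with peak time
    calibrated to the photocurrent-filter group mean; additive noise has SD
    ``noise_frac`` times the clean response SD.  Returns per cell a dict
    with 'stimulus', 'response' (Recording) and 'true_peak_ms'.
    """
    tgt = calib.CONE_FILTER_KINETICS[cone_type]
    fwhm_guess = tgt.fwhm if tgt.fwhm else 0.82 * tgt.time_to_peak
    base = calib.calibrate_template(tgt.time_to_peak, fwhm_guess)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    scales = jittered_scales(n_cells, cell_ttp_sd_ms / tgt.time_to_peak, rng)
    out = []
    for i, k in enumerate(scales):
        filt = LinearFilter.from_template(
            base.time_scaled(k), sampling_rate, duration_ms=400.0, gain=50.0, sign=-1.0
        )
        stim = gaussian_noise_stimulus(
            Stimulus(kind="gaussian_noise", mean_level=background, duration=duration,
                     sampling_rate=sampling_rate, contrast=contrast, bandwidth=bandwidth,
                     seed=int(rng.integers(2**31)))
        )
        from scipy.signal import fftconvolve

        clean = fftconvolve(stim - stim.mean(), filt.weights, mode="full")[: len(stim)]
        resp = clean + noise_frac * clean.std() * rng.standard_normal(len(stim))
        out.append(
            {
                "stimulus": stim,
                "response": Recording(samples=resp, sampling_rate=sampling_rate,
                                      modality="current", background=background,
                                      cone_type=cone_type, cell_id=f"{cone_type}f{i:03d}"),
                "true_peak_ms": tgt.time_to_peak * k,
            }
        )
    return out


def sbc_ensemble(
    channel: str = "lm_off",
    backgrounds: tuple = (1000.0, 10000.0),
    n_cells: int = 6,
    seed: int = 0,
    duration: float = 600.0,
    sampling_rate: float = 1_000.0,
    cell_jitter_sd_ms: float = 1.5,
    max_rate: float = 0.1,
    threshold_sd: float = 1.0,
    spread_sd: float = 0.5,
) -> list[dict]:
    """Simulated SBC spike trains at two backgrounds for one stimulus channel.

    Ground-truth filter peak times follow the calibrated SBC entries, with
    recentred per-cell, per-background jitter; spikes come from an LN
    cascade with a Gaussian-CDF nonlinearity (threshold ``threshold_sd``
    generator-SDs above mean, probabilities per 1 ms bin).  Returns per cell
    a dict {background: {'stimulus', 'spikes', 'true_peak_ms'}}.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 14]))
    sign = -1.0 if channel == "lm_off" else 1.0
    jit = {
        bg: calib.SBC_FILTER_KINETICS[(channel, float(bg))].time_to_peak
        * (jittered_scales(n_cells, cell_jitter_sd_ms
                           / calib.SBC_FILTER_KINETICS[(channel, float(bg))].time_to_peak,
                           rng) - 1.0)
        for bg in backgrounds
    }
    cells = []
    for i in range(n_cells):
        per_bg = {}
        for bg in backgrounds:
            tgt = calib.SBC_FILTER_KINETICS[(channel, float(bg))]
            ttp_i = tgt.time_to_peak + jit[bg][i]
            base = calib.calibrate_template(tgt.time_to_peak, tgt.fwhm)
            params = base.time_scaled(ttp_i / tgt.time_to_peak)
            filt = LinearFilter.from_template(params, sampling_rate,
                                              duration_ms=300.0, gain=1.0, sign=sign)
            stim = gaussian_noise_stimulus(
                Stimulus(kind="gaussian_noise", mean_level=1.0, duration=duration,
                         sampling_rate=sampling_rate, contrast=0.5, bandwidth=60.0,
                         seed=int(rng.integers(2**31)))
            )
            from scipy.signal import fftconvolve

            gen = fftconvolve(stim - stim.mean(), filt.weights, mode="full")[: len(stim)]
            g_sd = gen.std()
            filt = LinearFilter(filt.weights / g_sd, sampling_rate)
            nl = NonlinearityParams(max_rate=max_rate, center=threshold_sd,
                                    spread=spread_sd)
            spikes = simulate_sbc_spikes(
                s_filter=filt if channel == "s_on" else
                LinearFilter(-filt.weights, sampling_rate),
                lm_filter=filt if channel == "lm_off" else
                LinearFilter(-filt.weights, sampling_rate),
                nonlinearity=nl,
                stimulus=stim,
                channel="lm" if channel == "lm_off" else "s",
                seed=int(rng.integers(2**31)),
            )
            per_bg[bg] = {"stimulus": stim, "spikes": spikes, "true_peak_ms": ttp_i}
        cells.append(per_bg)
    return cells


def calibrate_single_photon_amplitude(
    cone_type: str,
    template: FlashTemplateParams,
    noise: NoiseSpec,
    background: float = 500.0,
    band_lo: float = 2.0,
    band_hi: float = 16.0,
) -> float:
    """Single-photon amplitude sizing the Poisson component to the calibrated
    flash-band noise factor.

    Solves a in  background * a² * 2∫_band |H_unit(f)|² df =
    (factor - 1) * 2∫_band cellular(f) df, where factor is the calibrated
    (background / darkness) flash-band power ratio for the cone type.
    """
    factor, _sem, _n = calib.NOISE_FLASH_BAND_FACTORS[cone_type]
    f = np.linspace(band_lo, band_hi, 201)
    p_cell = np.trapezoid(noise.cellular_psd(f), f)
    h2 = np.trapezoid(np.abs(template_transfer(template, f, dt_ms=0.1)) ** 2, f)
    if p_cell <= 0 or h2 <= 0:
        raise ValueError("cellular band power and template spectrum must be positive")
    return float(np.sqrt((factor - 1.0) * p_cell / (background * h2)))


def noise_ensemble(
    cone_type: str = "S",
    background: float = 500.0,
    n_cells: int = 14,
    seed: int = 0,
    duration: float = 60.0,
    sampling_rate: float = 10_000.0,
) -> list[dict]:
    """Noise recordings in darkness, on a background, and in saturating light.

    The Poisson photon-noise component is sized per cell so the expected
    flash-band power ratio (background / darkness) equals the calibrated
    factor for the cone type.  Returns per cell a dict usable directly by
    ``noise_vs_background`` ({0.0, background, 'saturating'} keys).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15]))
    base = calib.template_for(cone_type, 5000.0)
    noise = NoiseSpec(instrumental_level=5e-5, cellular_scales=(2e-3,),
                      cellular_corners=(20.0,))
    spa = calibrate_single_photon_amplitude(cone_type, base, noise, background)
    out = []
    for i in range(n_cells):
        spec = ConeSimSpec(
            cone_type=cone_type,
            background=background,
            template=base,
            single_photon_amplitude=spa,
            noise_model=noise,
            sampling_rate=sampling_rate,
            seed=int(rng.integers(2**31)),
            cell_id=f"{cone_type}n{i:03d}",
        )
        dark_spec = ConeSimSpec(**{**spec.__dict__, "background": 0.0,
                                   "seed": int(rng.integers(2**31))})
        sat_spec = ConeSimSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31))})
        out.append(
            {
                0.0: simulate_noise_recording(dark_spec, duration, "darkness"),
                background: simulate_noise_recording(spec, duration, "background"),
                "saturating": simulate_noise_recording(sat_spec, duration, "saturating"),
            }
        )
    return out
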