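"""Noise spectral analysis, band powers, thresholds."""

import numpy as np
import pytest

from conephys.noise import (
    BandDefinition,
    PSDEstimate,
    band_power,
    compute_psd,
    detection_threshold,
    flash_response_psd,
    isolate_cellular_noise,
    noise_effective_isomerizations,
    noise_vs_background,
)
from conephys.recording import Recording
from conephys.simulate import ConeSimSpec, NoiseSpec, colored_noise
from conephys.template import FlashTemplateParams, template_transfer

FLASH_BAND = BandDefinition("flash_response", 2.0, 16.0)


class TestComputePsd:
    def test_sinusoid_power(self):
        fs, f0, amp = 1000.0, 50.0, 2.0
        t = np.arange(int(30 * fs)) / fs
        psd = compute_psd(amp * np.sin(2 * np.pi * f0 * t), fs, 1.0)
        near = BandDefinition("near", f0 - 3.0, f0 + 3.0)
        assert band_power(psd, near) == pytest.approx(amp**2 / 2, rel=0.02)

    def test_white_noise_parseval(self, rng):
        fs = 2000.0
        x = 1.7 * rng.standard_normal(int(100 * fs))
        psd = compute_psd(x, fs, 1.0)
        assert psd.total_power() == pytest.approx(x.var(), rel=0.05)

    def test_lorentzian_noise_matches_target_per_band(self, rng):
        fs = 2000.0
        target = lambda f: 0.05 / (1.0 + (f / 30.0) ** 2)
        x = colored_noise(target, int(100 * fs), fs, rng)
        psd = compute_psd(x, fs, 1.0)
        for lo, hi in [(1, 10), (10, 40), (40, 150), (150, 600)]:
            grid = np.linspace(lo, hi, 2001)
            expected = 2.0 * np.trapezoid(target(grid), grid)
            assert band_power(psd, BandDefinition("b", lo, hi)) == pytest.approx(
                expected, rel=0.10
            )

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            compute_psd(np.zeros(500), 1000.0, 1.0)

    def test_deterministic_for_fixed_input(self, rng):
        x = rng.standard_normal(10_000)
        a = compute_psd(x, 1000.0, 1.0)
        b = compute_psd(x, 1000.0, 1.0)
        assert np.array_equal(a.density, b.density)


class TestIsolation:
    def test_identical_inputs_give_zero_spectrum(self, rng):
        psd = compute_psd(rng.standard_normal(10_000), 1000.0, 1.0)
        diff = isolate_cellular_noise(psd, psd)
        assert np.all(diff.density == 0.0)

    def test_grid_mismatch_rejected(self, rng):
        a = compute_psd(rng.standard_normal(10_000), 1000.0, 1.0)
        b = compute_psd(rng.standard_normal(10_000), 1000.0, 0.5)
        with pytest.raises(ValueError, match="grid"):
            isolate_cellular_noise(a, b)

    def test_subtraction_is_unbiased(self, rng):
        """Mean isolated spectrum over replicates equals the generated
        cellular spectrum (within Monte-Carlo bands)."""
        fs, dur = 1000.0, 10.0
        instr = lambda f: np.full_like(np.asarray(f, float), 2e-3)
        cell = lambda f: 0.05 / (1.0 + (f / 15.0) ** 2)
        n = int(dur * fs)
        reps = []
        for _ in range(100):
            both = colored_noise(lambda f: instr(f) + cell(f), n, fs, rng)
            sat = colored_noise(instr, n, fs, rng)
            reps.append(
                isolate_cellular_noise(
                    compute_psd(both, fs, 1.0), compute_psd(sat, fs, 1.0)
                ).density
            )
        mean_density = np.mean(reps, axis=0)
        freqs = compute_psd(np.zeros(n), fs, 1.0).frequencies
        sel = (freqs > 1) & (freqs < 100)
        assert np.allclose(mean_density[sel], cell(freqs[sel]), rtol=0.12, atol=1e-4)

    def test_absent_cellular_component_centres_on_zero(self, rng):
        fs = 1000.0
        instr = lambda f: np.full_like(np.asarray(f, float), 1e-2)
        powers = []
        for _ in range(50):
            a = colored_noise(instr, int(10 * fs), fs, rng)
            b = colored_noise(instr, int(10 * fs), fs, rng)
            diff = isolate_cellular_noise(compute_psd(a, fs, 1.0), compute_psd(b, fs, 1.0))
            powers.append(band_power(diff, FLASH_BAND))
        powers = np.array(powers)
        assert abs(powers.mean()) < 4 * powers.std() / np.sqrt(len(powers))


class TestBandPower:
    def test_constant_density_rectangle(self):
        f = np.linspace(0.0, 100.0, 1001)
        psd = PSDEstimate(f, np.full_like(f, 0.01))
        assert band_power(psd, FLASH_BAND) == pytest.approx(2 * 0.01 * 14.0, rel=1e-9)

    def test_disjoint_bands_are_additive(self):
        f = np.linspace(0.0, 200.0, 2001)
        psd = PSDEstimate(f, 0.01 / (1 + (f / 40) ** 2))
        lo = band_power(psd, BandDefinition("lo", 2.0, 16.0))
        hi = band_power(psd, BandDefinition("hi", 16.0, 100.0))
        union = band_power(psd, BandDefinition("u", 2.0, 100.0))
        assert lo + hi == pytest.approx(union, rel=1e-9)

    def test_lorentzian_closed_form(self):
        s, c = 0.05, 30.0
        f = np.linspace(0.0, 500.0, 200_001)
        psd = PSDEstimate(f, s / (1 + (f / c) ** 2))
        expected = 2 * s * c * (np.arctan(16.0 / c) - np.arctan(2.0 / c))
        assert band_power(psd, FLASH_BAND) == pytest.approx(expected, rel=5e-3)

    def test_band_outside_grid_rejected(self):
        f = np.linspace(0.0, 100.0, 101)
        with pytest.raises(ValueError, match="outside"):
            band_power(PSDEstimate(f, np.ones_like(f)), BandDefinition("x", 50.0, 200.0))


class TestNoiseVsBackground:
    def _recs(self, spec, dur=20.0):
        from conephys.simulate import simulate_noise_recording

        dark = ConeSimSpec(**{**spec.__dict__, "background": 0.0, "seed": spec.seed + 1})
        sat = ConeSimSpec(**{**spec.__dict__, "seed": spec.seed + 2})
        return {
            0.0: simulate_noise_recording(dark, dur, "darkness"),
            spec.background: simulate_noise_recording(spec, dur, "background"),
            "saturating": simulate_noise_recording(sat, dur, "saturating"),
        }

    def test_background_without_poisson_is_flat(self, s_cone_template):
        noise = NoiseSpec(include_poisson_component=False)
        spec = ConeSimSpec("S", 500.0, s_cone_template, 0.03, noise, 5000.0, 31)
        summary = noise_vs_background(self._recs(spec))
        vals = summary.normalized_powers["flash_response"]
        assert vals[list(summary.backgrounds).index(0.0)] == pytest.approx(1.0)
        assert np.allclose(vals, 1.0, atol=0.15)

    def test_missing_saturating_condition_rejected(self, s_cone_template):
        spec = ConeSimSpec("S", 500.0, s_cone_template, 0.03, NoiseSpec(), 5000.0, 3)
        recs = self._recs(spec)
        recs.pop("saturating")
        with pytest.raises(ValueError, match="saturating"):
            noise_vs_background(recs)


class TestFlashResponsePsd:
    def test_quadratic_amplitude_scaling(self, generic_template):
        base = flash_response_psd(generic_template)
        doubled = flash_response_psd(
            FlashTemplateParams(2 * generic_template.alpha, generic_template.t_rise,
                                generic_template.t_decay, generic_template.t_osc,
                                generic_template.phi)
        )
        assert np.allclose(doubled.density, 4 * base.density, rtol=1e-10)

    def test_time_scaling_compresses_frequency_axis(self, generic_template):
        k = 2.0
        freqs = np.linspace(1.0, 100.0, 51)
        slow = flash_response_psd(generic_template.time_scaled(k), freqs=freqs)
        fast = flash_response_psd(generic_template, freqs=k * freqs)
        assert np.allclose(slow.density, k**2 * fast.density, rtol=5e-3)

    def test_matches_quadrature_oracle(self, generic_template):
        freqs = np.array([0.5, 3.0, 11.0, 47.0, 150.0, 390.0])
        dt = 0.01
        t = np.arange(0.0, 600.0, dt)
        from conephys.template import evaluate_template

        f_t = evaluate_template(generic_template, t)
        oracle = np.array(
            [abs(np.sum(f_t * np.exp(-2j * np.pi * w * t * 1e-3)) * dt * 1e-3) ** 2
             for w in freqs]
        )
        est = flash_response_psd(generic_template, freqs=freqs)
        assert np.allclose(est.density, oracle, rtol=1e-3)


class TestThresholds:
    def _spr(self, template, fs, amp=0.03):
        t = np.arange(0.0, 400.0, 1e3 / fs)
        from conephys.template import evaluate_template

        return amp * evaluate_template(template, t)

    def test_zero_noise_gives_zero_threshold(self, generic_template):
        fs = 1000.0
        noise = Recording(samples=np.zeros(int(5 * fs)), sampling_rate=fs)
        q = detection_threshold(self._spr(generic_template, fs), noise,
                                sampling_rate=fs)
        assert q == 0.0

    def test_threshold_linear_in_noise_sd(self, generic_template, rng):
        fs = 1000.0
        spr = self._spr(generic_template, fs)
        base = rng.standard_normal(int(20 * fs))
        q1 = detection_threshold(
            spr, Recording(samples=base, sampling_rate=fs), sampling_rate=fs
        )
        q2 = detection_threshold(
            spr, Recording(samples=2 * base, sampling_rate=fs), sampling_rate=fs
        )
        assert q2 == pytest.approx(2 * q1, rel=1e-9)

    def test_matches_grid_search_oracle(self, generic_template, rng):
        fs = 1000.0
        spr = self._spr(generic_template, fs)
        noise = Recording(samples=0.1 * rng.standard_normal(int(20 * fs)),
                          sampling_rate=fs)
        q = detection_threshold(spr, noise, sampling_rate=fs)
        # brute-force: scan q until response power crosses the noise power
        from conephys.noise import _window_noise_power

        p_noise = _window_noise_power(noise, 0.2)
        grid = np.linspace(0.5 * q, 2.0 * q, 20001)
        w = int(0.2 * fs)
        p_resp = np.mean(spr[:w] ** 2)
        q_oracle = grid[np.argmin(np.abs(grid**2 * p_resp - p_noise))]
        assert q == pytest.approx(q_oracle, rel=0.01)

    def test_zero_response_rejected(self, rng):
        fs = 1000.0
        noise = Recording(samples=rng.standard_normal(int(5 * fs)), sampling_rate=fs)
        with pytest.raises(ValueError, match="zero amplitude"):
            detection_threshold(np.zeros(1000), noise, sampling_rate=fs)


class TestNoiseEffectiveIsomerizations:
    def _psds(self, generic_template, scale):
        flash = flash_response_psd(generic_template)
        cell = PSDEstimate(flash.frequencies, scale * flash.density)
        return flash, cell

    def test_equal_powers_give_one_rstar(self, generic_template):
        flash, cell = self._psds(generic_template, 1.0)
        assert noise_effective_isomerizations(flash, cell, FLASH_BAND) == pytest.approx(1.0)

    def test_quadrupled_noise_doubles_value(self, generic_template):
        flash, cell = self._psds(generic_template, 4.0)
        assert noise_effective_isomerizations(flash, cell, FLASH_BAND) == pytest.approx(2.0)

    def test_matches_grid_search_oracle(self, generic_template):
        flash, cell = self._psds(generic_template, 2.7)
        val = noise_effective_isomerizations(flash, cell, FLASH_BAND)
        p_resp = band_power(flash, FLASH_BAND)
        p_noise = band_power(cell, FLASH_BAND)
        grid = np.linspace(0.1, 10.0, 100_001)
        oracle = grid[np.argmin(np.abs(grid**2 * p_resp - p_noise))]
        assert val == pytest.approx(oracle, rel=0.01)

    def test_monotone_in_noise_spectrum(self, generic_template):
        flash, cell = self._psds(generic_template, 1.0)
        bumped = PSDEstimate(cell.frequencies, cell.density * 1.3)
        assert noise_effective_isomerizations(
            flash, bumped, FLASH_BAND
        ) > noise_effective_isomerizations(flash, cell, FLASH_BAND)

    def test_nonpositive_noise_rejected(self, generic_template):
        flash, cell = self._psds(generic_template, 0.0)
        with pytest.raises(ValueError, match="positive"):
            noise_effective_isomerizations(flash, cell, FLASH_BAND)
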