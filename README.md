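# conephys

Analysis and simulation of primate cone photoreceptor light responses.

Short-wavelength (S) cones feed a dedicated chromatic pathway, and their
responses differ from those of L and M cones: they peak later, change their
kinetics far less as background light increases, and carry relatively more
noise at low light levels. `conephys` packages the analysis chain needed to
quantify those differences from patch-clamp and extracellular recordings —
and, because such recordings are scarce, a calibrated synthetic-recording
generator so that every estimator can be validated against known ground
truth. It is aimed at retinal neurophysiologists and modellers who need
reproducible kinetic, spectral and LN-model summaries of photoreceptor and
ganglion-cell data.

## The model

The core waveform is the parametric flash-response template

    f(t) = α · (t/τ_r)⁴ / (1 + (t/τ_r)⁴) · e^(−t/τ_d) · cos(2πt/τ_o + φ),  t ≥ 0

a sigmoidal rise, exponential recovery, and slow cosine capturing the
undershoot. Everything kinetic is built on it:

- **Flash kinetics** — least-squares template fits; three time-to-peak
  estimators (argmax, truncated-Gaussian fit over ±10 ms, template fit);
  FWHM by interpolated half-maximum crossings; per-cell time-to-peak
  ratios across backgrounds; Weber adaptation fits
  γ_B/γ_D = 1/(1 + I_B/I_0).
- **Frequency tuning** — fixed-frequency sinusoid fits
  y = a·sin(2πft + b) + c, contrast-normalised tuning curves, fits of the
  template power spectrum under the loss Σ[log(F(ω_i)/D(ω_i))]², and the
  frequency where the fitted curve falls to 10% of its maximum.
- **Noise analysis** — Welch two-sided PSDs; instrumental-noise isolation by
  subtracting the saturating-light spectrum; band powers (flash-response
  band 2–16 Hz, high-frequency band 20–394 Hz) normalised to darkness;
  detection thresholds and noise-effective isomerizations.
- **LN models** — reverse-correlation linear filters by regularised spectral
  division F(ω) = ⟨S*R⟩/(⟨|S|²⟩ + floor) (robust to the band-limited 0–60 Hz
  stimulus), spike detection, Gaussian-CDF spiking nonlinearities, and
  filter peak-time shifts between backgrounds.
- **Stimulus design** — flashes, contrast-ramped sinusoids, band-limited
  Gaussian noise (50% contrast SD/mean), and silent-substitution LED
  solutions built from visual-pigment nomograms and an LED→isomerization
  matrix (collecting area 0.37 µm²).
- **Synthetic data** — templates calibrated per cone type and background to
  published group statistics; coloured noise with instrumental, cellular
  (Lorentzian) and Poisson photon-absorption components; LN-cascade spike
  trains.

## Worked example

```python
from conephys import ensembles
from conephys.pipeline import kinetics_report

for cone_type in ("S", "M", "L"):
    recs = ensembles.flash_ensemble(cone_type, 5000.0, n_cells=8,
                                    n_trials=10, seed=0)
    rep = kinetics_report(recs)
    print(f"{cone_type}: ttp {rep.time_to_peak_ms.mean():.1f} ms, "
          f"FWHM {rep.fwhm_ms.mean():.1f} ms")
```

prints

```
S: ttp 45.4 ms, FWHM 37.5 ms
M: ttp 36.4 ms, FWHM 30.2 ms
L: ttp 36.9 ms, FWHM 32.2 ms
```

— the S-cone flash response at a 5000 R*/s background peaks ~9 ms later and
lasts ~5–7 ms longer than the L/M responses; the numbers are ensemble means
of the truncated-Gaussian peak-time estimator and the interpolated FWHM over
noisy simulated trial averages. The `examples/` directory has one short
script per capability (flash kinetics, tuning, noise, LN models, cone
isolation), and a thin CLI (`conephys simulate|fit-flash|run-all`) wraps the
pipeline for shell use.

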