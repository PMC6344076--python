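# Methods

This note records the models, estimator conventions and design choices
behind `conephys`, in the spirit of a package methods appendix. Times are
milliseconds in all kinetic APIs and reports, seconds in trace containers;
light levels are photon-absorption rates (R*/cone/s); power spectra use the
two-sided convention (pA²/Hz or mV²/Hz) on a nonnegative frequency grid,
with band powers carrying the ±frequency symmetry factor 2 so they are
physical variances.

## Flash-response template

The canonical waveform is
`f(t) = α·(t/τ_r)⁴/(1+(t/τ_r)⁴)·exp(−t/τ_d)·cos(2πt/τ_o + φ)` for `t ≥ 0`.
It vanishes at the origin, decays to zero, and the slow cosine produces the
post-peak undershoot seen in cone responses. Template fits use multi-start
bounded nonlinear least squares (grid over τ_r ∈ {5,15,30} ms,
τ_d ∈ {10,30,100} ms, φ ∈ {0, −π/2}, τ_o initialised large) because the
waveform is multimodal in the oscillation parameters. Traces are
baseline-subtracted (mean of the 50 ms before flash onset) and
polarity-rectified so the dominant deflection is positive — voltage
responses hyperpolarise — with the sign folded back into α.

## Time to peak and FWHM

Three estimators are provided: the raw argmax; a truncated-Gaussian fit
(Gaussian plus offset over ±10 ms around the raw extremum, window
configurable); and the peak of the template fit by dense evaluation. The
Gaussian fit weights samples by squared amplitude above the window minimum:
a symmetric Gaussian fitted to an asymmetric waveform is otherwise biased by
up to ~0.6 ms toward the heavier flank, and the weighting keeps that bias
below ~0.4 ms on all calibrated shapes while retaining the estimator's
robustness to single noisy samples. Exact agreement among all three
estimators on noiseless input is not attainable — the Gaussian is the wrong
model family near an asymmetric peak — so the tests pin argmax and
template-fit to one sample period of each other and the Gaussian estimator
to 0.5 ms of a dense-grid oracle.

FWHM interpolates the two half-maximum crossings between samples. Two
refinements guard against noise: the peak value comes from a local quadratic
fit (±3 ms) so a single high sample does not inflate the half level, and
each crossing is refined by a linear regression over ±4 ms. Under
correlated trial noise the plain first-sample-below-half rule is biased
several milliseconds narrow (a noise dip near the crossing truncates the
walk early); the regression line averages zero-mean noise and removes the
bias at the cost of a small (<1%) curvature bias on strongly curved edges.
Both refinements can be disabled (`refine_window_ms=0`).

## Tuning curves and the spectral fit

Response amplitude at each stimulus frequency is the `a` of an exact linear
least-squares fit `y = a·sin(2πft+b)+c` with `f` fixed, divided by the
stimulus contrast (contrast rises with frequency so high-frequency responses
stay measurable; division makes amplitudes comparable). Per-cell curves are
normalised to unit maximum before averaging. Under linearity the tuning
curve is the amplitude spectrum of the impulse response, and curves are
fitted with the template's spectrum under the squared-log-ratio loss
`Σ[log(F(ω_i)/D(ω_i))]²`; a signed sum of log ratios is unbounded below and
cannot produce a fit, so the squared form is used. The residuals are
mean-centred, i.e. an amplitude scale is solved analytically, making the fit
invariant to common rescaling of the data. By default `F` is the *power*
spectrum of the template fitted to amplitude data (the literal reading of
fitting "the power spectrum" to a tuning curve); `spectrum="amplitude"`
switches to the amplitude spectrum. The cutoff frequency is the first point
above the fitted curve's peak where it falls to 10% of maximum, by
log-linear interpolation on a dense grid; the search starts at the argmax to
avoid low-frequency roll-off ambiguity, and cutoffs beyond the last probe
frequency are flagged extrapolated.

The same loss (with the dark gain solved analytically) fits the Weber
adaptation curve `γ_B/γ_D = 1/(1+I_B/I_0)`; fitted curves are rescaled so
the dark gain is exactly 1, and by construction the fitted gain at
`I_B = I_0` is half the dark gain.

## Noise spectra and derived quantities

PSDs are segment-averaged periodograms (Hann window, 50% overlap, 1 s
segments by default; all configurable) converted to the two-sided
convention. Cellular noise is isolated by subtracting the saturating-light
spectrum — saturating light shuts down phototransduction, leaving
instrumental noise — under the assumption that the two sources are
independent. Negative difference bins are retained so band powers stay
unbiased. Band powers are `2×` the trapezoidal integral of the two-sided
density with interpolated band edges. The flash-response spectrum is the
squared Fourier magnitude of the continuous template fit (an energy
spectrum; only band-power *ratios* against noise are used, so the units
cancel). Detection threshold is the flash strength `q` whose response power
(mean squared single-photon response over a 200 ms window, scaled by `q²`)
equals the mean within-window variance of the 3 kHz-low-passed noise, i.e.
`q = √(P_noise/P_response)`; noise-effective isomerizations apply the same
square-root ratio to band powers. Both are therefore linear in noise SD and
monotone in any pointwise increase of the noise spectrum.

## Linear filters and LN models

Filters are estimated by spectral division
`F(ω) = ⟨S*(ω)R(ω)⟩ / (⟨|S(ω)|²⟩ + floor)` averaged over half-overlapping
Hann segments, with the floor defaulting to 1% of the peak stimulus power.
Plain cross-correlation is biased by the autocorrelation of the band-limited
(0–60 Hz) stimulus; the division undoes it, and the floor controls the
out-of-band amplification. Kernels are stored as discrete-convolution
weights (continuous kernel = weights × sampling rate). For spiking cells
the same estimator runs on the 1 ms-binned binary spike vector; for a
Gaussian stimulus and a static nonlinearity this recovers the true filter up
to a positive scale (Bussgang), and the scale trades off against the
nonlinearity's input axis — the cascade is tested for exactly this
invariance. Nonlinearities are per-bin spike probabilities over 20
equal-occupancy generator-signal bins, fitted by weighted least squares with
a scaled Gaussian CDF; a fitted spread far above the generator SD flags a
flat (unresolvable) nonlinearity. Spike detection high-passes at 300 Hz
(zero-phase), thresholds at 5 robust SDs (median absolute deviation), and
merges threshold-crossing runs closer than the refractory period (2 ms
default) into single events timed at the merged extremum. Background shifts
are differences of template-fit peak times of the polarity-rectified
filters, low background minus high.

## Stimuli and cone isolation

Sinusoids are `mean·(1+c·sin 2πft)` (contrast = amplitude/mean); Gaussian
noise is white noise hard-masked in the frequency domain to 0–60 Hz and
scaled to SD = contrast × mean (contrast = SD/mean, default 0.50). Negative
light is clipped and logged; at 50% contrast the mean sits 2 SD above zero,
so ~2% of samples clip and the realised SD runs ~3% under nominal — the
documented cost of enforcing non-negativity. Flashes default to 10 ms.

Cone spectral sensitivities use an A1-pigment nomogram (α plus β band) with
default λmax 430/531/561 nm; the nomogram peak is normalised to exactly 1.
LED spectra default to Gaussian profiles at 406/515/640 nm (FWHM
configurable; measured spectra can be loaded from CSV). The LED→cone matrix
holds collecting-area-scaled overlap integrals; its inverse maps target
per-cone rate modulations to LED drives, and any drive leaving [0, max] is
a gamut error naming the LED. Silent-substitution round trips recover
commanded contrasts to 1e-8 and null the silenced cones to 1e-10.

## The synthetic-data generator

The generator emulates what the analyses assume, not phototransduction
biochemistry: flash responses are scaled templates plus additive coloured
noise; continuous noise is the sum of an instrumental component
(first-order spectrum, corner 3 kHz — present in saturating light), a
background-independent cellular component (sum of Lorentzians, default
corner 20 Hz; the shape is configurable since it is a modelling choice), and
on a background a Poisson photon-absorption component with spectrum
`rate × |H_single_photon(f)|²` (Campbell's theorem), where the single-photon
response is the template scaled to the per-R* amplitude. All noise is
synthesised by frequency-domain shaping of white Gaussian noise — exact
target spectrum in expectation — so the Poisson term is Gaussian with the
correct second-order statistics, which is all the spectral pipeline
measures. Spikes are per-bin Bernoulli draws (1 ms bins) from a Gaussian-CDF
nonlinearity applied to the generator signal. Fixed seed and spec give
bit-identical output; independent sub-streams are derived per purpose.

What the generator does *not* emulate: response saturation and dynamic
adaptation within a trial, spike-history dependence (refractoriness,
bursting), non-Gaussian noise statistics, instrumental drift, and cell
death/washout. Passing tests therefore demonstrate that the estimators
recover the encoded ground truth under the assumed signal and noise model,
not that real recordings satisfy those assumptions.

### Calibration tables

`conephys.calibration` ships per-cone-type, per-background kinetic targets.
Printed group statistics (with sem and n) populate the entries where they
exist; the remaining entries are package choices, fixed once: the S-cone
backgrounds at 1000 and 10,000 R*/s encode a ~4% relative peak-time change
over the 50-fold background range (inside the documented <10% bound), the
L/M entries encode the documented ~30% speeding, and unprinted FWHM values
follow the same shape family. A two-parameter solver (τ_r = τ_d, free τ_o,
φ = −π/4) realises any feasible (peak time, FWHM) pair; within this family
the overall time scale sets the peak time and the cosine period sets the
width-to-peak ratio. The tuning-filter calibration solves for the time
scale at which the *full noiseless pipeline* (probe frequencies → spectral
fit → cutoff) returns the target cutoff, so pipeline and calibration share
one convention. The Poisson-component amplitude is solved in closed form so
the expected flash-band power ratio at 500 R*/s equals the encoded factor.

### Ensembles

Population builders draw per-cell kinetic scale factors (e.g. peak-time SD
5 ms for flash ensembles, 3 ms for filter ensembles, 1.5 ms for SBC
filters) and recentre them so the realised ensemble mean equals the
calibration target exactly: the ensembles exist to encode group statistics,
and recentring removes the sampling error a finite draw would otherwise add
to the encoded mean. Trial noise is 10% of the response peak for flash
trials; Gaussian-noise responses carry additive noise at 25% of the response
SD; SBC simulations use 10 min of 50%-contrast noise per background with
~19 spikes/s. Flash-trial ensembles omit the Poisson component because
their noise level is specified directly; the noise-recording ensembles,
where photon noise is the quantity under study, include it.

### Problem sizes

Default analysis and test sizes are chosen so the whole suite runs in about
a minute on one core: 36-cell flash ensembles with 10 trials of 0.5 s at
10 kHz; 15 tuning cells × 7 frequencies × 4 s at 2 kHz; 12 filter cells ×
60 s at 10 kHz; 6 SBCs × 2 backgrounds × 600 s at 1 kHz; 14 noise cells ×
3 conditions × 60 s at 10 kHz. Monte-Carlo oracle tests use 30–500
replicates depending on per-replicate cost.

## Numerical conventions and degenerate inputs

Template transforms are evaluated from a cached zero-padded FFT
(≤0.1 Hz grid) of the densely sampled waveform, interpolated to requested
frequencies; relative accuracy is ~1e-3 near the peak and a few ×1e-5 of the
peak in the tails. Ties in argmax break to the earliest sample (logged).
Flat traces raise degenerate-fit errors; truncated responses (half-maximum
never re-crossed) raise; missing reference backgrounds, mismatched frequency
grids and sampling rates, out-of-gamut drives and singular matrices raise
with messages naming the offender. Dark-gain and tuning fits require
strictly positive data for the log-ratio loss. Seeds derive from
`SeedSequence([seed, stream])`; everything downstream of a fixed seed is
deterministic, including CSV report bytes.

## Known limitations

- Estimator biases, though controlled, are not zero: the truncated-Gaussian
  peak estimator carries a small shape-dependent bias, and the FWHM crossing
  refinement trades noise bias for a small curvature bias.
- The spectral-division filter estimate is unconstrained outside the
  stimulus band; only its in-band shape (and hence peak time) is meaningful.
- The Weber fit assumes the template amplitude tracks gain linearly; it does
  not model response compression within a flash family.
- The nomogram is a fixed analytic template; real macular pigment and lens
  filtering are not modelled, so absolute isomerization rates from real LED
  calibrations should be computed with measured spectra.
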