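# Methods

## Signal model and preparation

All preparation starts from raw fluorescence, the photon count of the
entire field of view. Background fluorescence — the field with the cell
absent — is subtracted once, as a scalar per channel, before any other
step; if a background *trace* is supplied it is reduced to its mean first,
on the grounds that a steady background carries a single level. The
signal-kind graph (`raw → background_subtracted → {ratio, f_over_f0,
calcium_nM}`) is enforced on the `Trace` container so a signal can never
be background-subtracted twice or calibrated without subtraction.

Three prepared representations are supported. For dual-channel
(ratiometric) indicators, `Ratio = F_nom/F_denom` sample for sample, with
per-channel backgrounds removed inside the operation; any
background-subtracted denominator sample ≤ 0 aborts with the sample index
(the ratio is meaningless there). For single-channel indicators,
calibration `[Ca] = F·Kd/(Fmax − F)` maps fluorescence to concentration;
it diverges as F → Fmax, so any saturated sample aborts the calibration
rather than emitting negative concentrations, while samples ≤ 0 are
clamped to 0 nM with a warning. The pseudo-ratio `F/F₀` divides by the
diastolic fluorescence F₀, defined either as a shared constant or as the
mean over a cursor-flanked baseline region per treatment; both paths are
exposed. Dual-wavelength ratio-to-[Ca] calibration (Grynkiewicz
Rmin/Rmax) is deliberately out of scope: ratios are reported as relative
signals.

Every preparation preserves the time vector and sample count exactly, and
`[Ca]` is strictly increasing in F on (0, Fmax), which the tests assert
as properties.

## Levels

Diastolic and systolic levels emulate the two Y-axis cursors: the manual
path stores user-supplied levels verbatim; the automated path takes the
*mean* over a flat baseline window for diastole and the *max* over a peak
window for systole, matching how a user aligns one cursor with the
resting segment and one with the crest. Amplitude is their difference,
asserted at construction. A peak window whose maximum falls below the
baseline mean flags the measurement instead of failing — on a noisy
signal this is a mis-chosen window, and the batch should continue. The
max statistic carries a positive noise bias of order σ·√(2·ln m) for m
window samples; with noise at 2% of amplitude the measured amplitude is
reliable to about 10%.

## Decay regression

The decay window is cursor-flanked, re-zeroed in time (only elapsed time
enters the model, making the fit invariant to the window's absolute start
time) and must contain at least 6 samples so that even the 5-parameter
double model is overdetermined. Optionally the baseline-cursor level is
subtracted from the window first ("zero fit range"), purely to condition
the optimizer; the reported Y₀ is re-offset, and the fitted rate
constants agree with the un-zeroed fit to better than 1e-6 relative
(tested).

Initial guesses: Y₀ starts at the baseline cursor, A at peak-minus-
baseline. The starting rate constant is 1/τ with τ read off the curve as
the elapsed time to first fall below `Y₀ + (peak − Y₀)/e` — exact for a
clean monoexponential, and within 25% under realistic noise. If the level
is never crossed, τ falls back to half the window duration and a
`TauFallbackWarning` is emitted. With smart prediction disabled, τ starts
at one fifth of the window duration. The double-model start splits the
single guess through four positive user constants, `A₁ = A/a, A₂ = A/b,
k₁ = k/c, k₂ = k/d`, defaulting to (2, 2, 0.5, 2): amplitudes split
evenly, one component seeded twice as fast and one half as fast as the
single-model rate. The constants are fully configurable, so a
multiplicative reading of the splitting convention is also reachable.

Minimization is bounded-iteration nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective), default cap
1000 function evaluations and tolerance 1e-10 on parameters and cost.
Rate constants are bounded below by 1e-12 (decays, not growths);
amplitudes and Y₀ are unconstrained in sign so inverted signals fit.
Optimizer failure never raises: the result carries `converged=False` with
the initial guess echoed. Double-fit components are reported fast-first
(k₁ ≥ k₂); the model is symmetric under component exchange, so ordering
is purely a reporting convention. A zero-variance window yields NaN for
both R² statistics (flagged undefined rather than “perfect”).

Noiseless fits recover generating parameters at the realistic scales
(k ≈ 3.3e-3 /ms mono; k₁ = 1.7e-2, k₂ = 1.2e-3 /ms bi) to ≤ 1e-4
relative, and on small windows the optimum is never worse than an
exhaustive 21³ grid search around the truth — both asserted in the test
suite with the grid oracle implemented independently of the fitting path.

## Model comparison

Fitting both models on the identical window makes their statistics
directly comparable; the indicated best fit is the larger *adjusted* R²,
with ties (|Δ| < 1e-12) going to the single model by parsimony. A caveat
this package documents and measures: adjusted-R² selection between
nested models is equivalent to an F-test with threshold 1, a liberal
rule. On data generated by the *single* model with noise, the double
fit's SSE improvement is asymptotically χ²₂·σ², so the single model is
selected only with probability P(χ²₂ < 2) = 1 − e⁻¹ ≈ 63%, independent of
noise level and sample count; the acceptance script measures ~64% under
its conditions. On strongly biexponential data (k₁/k₂ ≈ 14) the double
model is selected essentially always. Practically: trust an indicated
*double* on mono-looking data less than an indicated single — or confirm
with the fitted component amplitudes, since a spurious second component
carries a near-zero amplitude. No F-test or AIC is provided; adjusted R²
is the contracted comparator.

## Synthetic transients

`TransientSpec`/`make_transient` generate one transient: a
saturating-exponential upstroke `baseline + amplitude·(1 − e^(−t/τ_up))`
with τ_up = 20 ms by default, a peak pinned at 5·τ_up (≥ 99% of nominal
amplitude, so the decay region is cleanly flankable), then a mono- or
biexponential decay from the actually-attained peak amplitude —
guaranteeing the decay segment satisfies the fitted model *exactly* when
noiseless, which is what closure tests rely on. Noise is additive, white
and Gaussian, seeded through `numpy.random.default_rng`; a constant
background offset is available for subtraction tests, and
`make_ratiometric_pair` embeds the waveform in a two-channel pair whose
noiseless ratio reproduces it exactly. Defaults sit at realistic myocyte
scales: baseline 1.0, amplitude 0.5 (an F/F₀-like signal), mono
k = 0.0033 /ms, bi k₁ = 0.017 / k₂ = 0.0012 /ms with an even amplitude
split, 1-ms sampling over 2–4 s sweeps.

What the generator does *not* emulate — and hence what passing tests do
not certify for real recordings: shot-noise variance scaling with signal,
photobleaching and dye-loss drift, motion artifacts, multi-beat trains
and alternans, and caffeine-response waveforms. One transient per trace
is assumed; there is no automatic transient segmentation.

## Problem sizes and runtime choices

Stochastic properties are checked at 100 seeded repeats (noisy recovery,
initial-guess quality), 50 per arm (model selection) and 10 treatments
(pipeline closure), with decay windows of ~1000–3900 samples; the full
suite runs in well under a minute. The noisy-recovery scenario uses
noise at 10% of amplitude on 1000-sample windows; the model-selection and
pipeline scenarios use 2% and 1%, the generator's "clean recording"
range. The acceptance script derives every per-run seed from its single
`--seed` argument.

## Interfaces

Traces travel as delimited text (time in ms — or seconds with a flag —
plus one or two value columns, explicit column mapping, never sniffed;
uniform sampling required within 1e-4 relative jitter, irregular traces
rejected rather than resampled). Collated results are one CSV row per
treatment with a stable column order; re-sending a label overwrites its
row. The batch driver takes a YAML config and isolates per-treatment
failures, reporting stage and label while the rest of the batch runs.
The original workflow's 10-transient capacity is a batch-size convention
here, not a limit.
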