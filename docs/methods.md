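# Methods

## The problem

Trial-averaged evoked responses in EEG/MEG can arise without any additive
evoked component: if an ongoing rhythm oscillates around a *non-zero mean*
(an offset `r`), then any modulation of its amplitude `A(t)` produces a
low-frequency baseline shift proportional to `A(t)·r`.  The oscillatory
part cancels across trials with random phases; the baseline-shift term does
not.  `oscbaseline` implements (i) a population simulator in which this
mechanism can be switched on and dialled, and (ii) the detection chain — the
baseline-shift index (BSI) — that measures the coupling between the alpha
amplitude envelope and the low-frequency signal in real or synthetic
recordings.

## Generative model

Each oscillator is

```
mu(t) = A(t) · [ A_alpha · sin(2π f_alpha t + θ_a)
                 + A_beta · sin(2π f_beta t + θ_b) + r ]
```

with defaults `A_alpha = 1`, `A_beta = 0.25`, `f_alpha = 10 Hz`,
`f_beta = 20 Hz`, `r = −0.4` (all a.u.), sampled at 1000 Hz on the
left-closed grid `t = 0, 1/fs, …, duration − 1/fs`, so means over integer
numbers of cycles are exact: a single oscillator with constant modulation
has time-mean exactly `r`.

**Beta phase.** The beta component is a phase-locked harmonic.  The default
rule is `θ_b = 2·θ_a + π/4`: with `f_beta = 2·f_alpha`, this is the only
rule that makes every oscillator's waveform a pure time shift of the same
comb-shaped template (a time shift τ advances the alpha phase by ωτ and the
beta phase by 2ωτ).  The literal alternative `θ_b = θ_a + π/4` is available
as `beta_phase_rule="shifted"`.

**Phases and synchrony.** Starting phases are drawn i.i.d. from a von Mises
distribution with mean `μ0` and concentration `κ`.  `κ = 1` models a
synchronous population (mean resultant length `I₁(1)/I₀(1) ≈ 0.45`, so the
macroscopic alpha amplitude grows ∝ N), `κ = 10⁻⁶` an asynchronous one
(uniform phases, random-phasor sum ∝ √N).  The offset term `A(t)·N·r` is
unaffected by `κ` — this asymmetry is the scientific point of the
synchrony contrast.

**Exact phasor reduction.** A compound epoch sums N equal-frequency
sinusoids; the sum is evaluated exactly through the complex resultant
`Z = Σ exp(iθ_i)`, making an epoch O(N + T) instead of O(N·T).  Unit tests
verify the reduction against brute-force per-oscillator summation.

**Noise.** Pink noise is synthesised in the frequency domain (magnitudes ∝
f^(−1/2), uniform random phases, DC bin zeroed, inverse transform, rescaled
to the target standard deviation); its log–log PSD slope is −1.0 ± 0.2 in
every test.  White Gaussian noise models the sensor/environment floor.  The
defaults (`pink_sigma = 10000`, `white_sigma = 3000` a.u.) set the
single-epoch alpha-band SNR to roughly 10 dB for the default synchronous
population of N = 30000; scaled-down runs scale the noise with N to hold
that SNR.

**Amplitude modulation.** `A(t)` is either constant, an inverted Gaussian
(trough depth 0.8 at mid-epoch; flank widths 0.1 s left / 0.2 s right,
modelling a fast suppression with slower recovery), an explicit trace, or —
for resting-state-like runs — a smooth stochastic envelope (`smooth_envelope`:
rectified Gaussian noise low-passed at 1 Hz, unit mean, floored at 0.2).

**Mixtures.** `simulate_mixture` projects source traces onto channels via
arbitrary weight vectors and adds white sensor noise plus, optionally,
*independent pink noise per channel*.  The per-channel pink background is
deliberate: the 1/f background of real recordings is spatially diverse.  If
instead all 1/f noise enters through the source's own topography, the noise
covariance becomes collinear with the signal direction and spatial-filter
polarity is undefined — an instructive failure mode, but not a realistic
one.  `single_source_mixture` and `two_source_mixture` package the standard
recovery fixtures (smooth single-lobe topographies, N = 300-scale
populations, κ = 1, stochastic envelopes) used throughout the tests.

**Seeding.** Every random draw comes from
`SeedSequence([seed, stream, index])` with fixed stream identifiers
(phases, pink, white, epoch, sensor, source), so any epoch or noise
component is bit-reproducible in isolation, and two runs that share a
master seed share everything except the quantity deliberately varied
(e.g. the synchrony contrast shares noise across κ settings).

## Spectral summaries

Spectra use Welch's method with 10-s Hann windows and 50% overlap (0.1 Hz
resolution).  The individual alpha peak is the argmax of the channel-average
spectrum within 8–13 Hz.  A peak is only *accepted* if the 1-Hz-boxcar-
smoothed spectrum exceeds both range endpoints by at least 10%: exactly
flat or monotone spectra always fail this test, and so do realistic
alpha-free (1/f) spectra, whose raw argmax is an arbitrary interior bin.
Rejected peaks are returned with `peak_found=False` and downstream analysis
stops with a distinct exit code.

Two scale-invariant power ratios summarise signal-to-noise:

* `Ra` — mean PSD within peak ± 1 Hz over the mean PSD of the two flanking
  bands;
* `Rlf` — mean PSD over 0.1–3 Hz divided by the mean PSD over 0.1–7 Hz.

Because these are ratios of band *means*, `Rlf` may exceed 1 when power
concentrates below 3 Hz (a 1 Hz line gives ≈ 2.4); it is positive, not
bounded by 1.

**Flank convention.** The flanking bands sit 2–3 Hz outside the *edges* of
the signal band (peak ± 1 Hz), i.e. `[peak−4, peak−3]` and
`[peak+3, peak+4]`.  The alternative of measuring offsets from the peak
itself (`[peak−3, peak−2]`, `[peak+2, peak+3]`) is a config switch
(`convention="peak"`); the same convention is reused by the SSD band design
so the covariate and the filter see the same noise bands.

## Spatio-spectral decomposition

SSD solves `C_s w = λ C_n w`, where `C_s` is the channel covariance of the
signal-band-filtered data (zero-phase order-2 Butterworth at peak ± 1 Hz)
and `C_n` the average covariance of the two flank-band-filtered data sets.
One second is trimmed from each end before covariance estimation to remove
filter transients.  Narrow-band covariances from finite data are
near-singular, so `C_n` is shrunk toward the scaled identity with the
smallest grid value γ ∈ {0, 10⁻⁶, …, 0.5} that brings its condition number
under 10⁶; if none does, the decomposition fails loudly.  Eigenvalues are
sorted descending; each filter column is flipped so its maximal-absolute
weight is positive; patterns (forward models) are
`P = C_s W (Wᵀ C_s W)⁻¹`.  The first five components (capped at the channel
count) are analysed further.

## The baseline-shift index

For a component trace and its individual alpha peak:

1. `V_alpha`: Hilbert amplitude envelope of the zero-phase order-2
   band-pass at peak ± 2 Hz;
2. `V_bs`: zero-phase order-4 low-pass at 3 Hz, optionally (default on)
   high-passed at 0.1 Hz to remove acquisition drift;
3. one second trimmed from each end;
4. samples assigned to 20 percentile bins of `V_alpha` (stable sort, ties
   broken by sample order, last bin holds the highest amplitudes); both
   traces averaged per bin;
5. BSI = Pearson correlation (and, as a second variant, the regression
   slope) over the 20 bin means.  A raw-sample variant (`use_bins=False`)
   exists for sensitivity analysis.

All filtering is forward–backward: any group delay between `V_alpha` and
`V_bs` would corrupt the pairing, so zero phase is non-negotiable even
though it doubles the effective filter order.  Filter padding is three
characteristic times (3/bandwidth for band filters, 3/cutoff otherwise) —
the library default of a few samples leaves narrow-band edge transients
that visibly corrupt short-epoch envelopes.

The binning step is what makes the BSI robust: components of `V_alpha`
that are absent from `V_bs` (noise, out-of-band envelope content) average
out within bins, and for jointly near-Gaussian fluctuations the conditional
bin means remain linearly related, so genuine coupling survives while the
correlation of incoherent parts collapses.

The sign of the BSI mirrors the sign of the oscillatory mean: a positive-`r`
rhythm shifts the baseline up when its amplitude grows.

**High-pass caveat.** The 0.1 Hz high-pass removes drift from `V_bs` but
not from `V_alpha` (the envelope is not high-passed), so on drift-free
synthetic signals whose modulation has sub-0.1 Hz content it slightly
*decorrelates* the pair.  The drift-free benchmark constructions therefore
run with the high-pass disabled; real-data pipelines keep it on.

## Permutation test

Significance comes from segment-shuffle surrogates: `V_bs` is cut at 4
uniformly drawn interior points into 5 contiguous segments (redrawn until
every segment is at most 90 s; if the trace is too long for that cap to be
satisfiable it is dropped with a warning), the segments are shuffled, and
the binned BSI is recomputed against the original envelope — 500
permutations by default.  Shuffling contiguous segments preserves the
marginal distribution and autocorrelation of `V_bs` while destroying its
alignment with the envelope.

The default p-value is the calibrated magnitude rule
`p = #(|BSI_perm| ≥ |BSI_obs|) / n_perm`, which rejects in the direction of
the observed sign and is uniform under the null (measured over 200
independent null pairs: rejection rate 0.065 at the 0.05 threshold,
Kolmogorov–Smirnov distance to U(0,1) of 0.06).  A literal one-sided count
in the direction of the observed sign (`alternative="directional"`) is also
provided; note that under a symmetric null it concentrates p on (0, 0.5)
and doubles the nominal false-positive rate (measured 0.12), so it should
be used only for comparison.  No +1 smoothing is applied, so p = 0 is
possible.

## Epoch averaging and the synchrony contrast

`E(t)` is the per-sample *sum* across epochs (a mean variant exists behind
a flag).  The mean alpha envelope is computed per epoch and then averaged.
Envelope modulation depth is `1 − mean(trough window)/mean(baseline
window)`, with defaults: baseline over 5–25% of the epoch, trough ± 50 ms
around the modulation centre, and the evoked offset measured over the final
20% of the epoch, away from the modulation trough.  No single-trial
baseline correction is applied by default, so the evoked offset retains the
`K·N·r·A(t)` term whose sign matches `r`.

At matched seeds the offset is synchrony-invariant (the two κ runs share
noise; the residual oscillatory term averages out over the integer number
of alpha cycles in the offset window), while the envelope modulation depth
collapses for asynchronous populations, whose macroscopic alpha amplitude
(∝ √N) sinks toward the noise floor.

## Problem sizes used in the test suite

The shipped tests run the full-scale mechanism at desk scale, chosen so
the full suite completes in a few minutes on one core: populations of
200–3000 oscillators (30000 available via config), 12–20 epochs (100 via
config), 60–300 s recordings at 200–1000 Hz, 40 end-to-end mixture runs,
200-null permutation calibration at 200 permutations, and 20-mixture SSD
recovery.  The synchrony contrast runs N = 3000, K = 20 with noise scaled
proportionally to N to preserve the full-scale single-epoch alpha SNR.

## What the synthetic data do and do not show

The generator reproduces the features the detection chain relies on:
narrow-band alpha with a harmonic, controllable oscillatory mean, slow
amplitude modulation, 1/f background, white sensor noise, phase-dispersed
populations and linear forward mixing.  It does not model biophysics
(no compartmental neurons, no realistic head model — mixing is an arbitrary
weight matrix), non-sinusoidal waveform diversity beyond the fixed
harmonic, non-stationary peak frequency, or artifacts (ocular, muscular,
line-noise transients).  Passing tests therefore demonstrate correctness of
the estimator and its calibration under the stated generative assumptions,
not robustness to every property of empirical recordings; the
amplitude-threshold rejector is a crude automatic stand-in for the manual
artifact screening that real studies perform.

## Numerical notes and degenerate inputs

* Band edges must lie strictly inside (0, fs/2); violations raise
  `ValueError` before any filtering.
* Constant traces make the Pearson correlation undefined and raise a
  degenerate-input error rather than returning NaN.
* Recordings with non-finite samples are rejected at construction, naming
  the offending channel.
* The Hilbert transform pads to the next fast FFT length and truncates.
* Percentile-bin edges sit at quantiles k/20 with stable ties, so bin
  counts differ by at most one sample and count-weighted bin means conserve
  the trace mean to machine precision.
* All operations are bit-reproducible under a fixed seed.

## Known limitations

* The BSI is a correlation over 20 points; with fewer than ~60 s of data
  its variance is substantial (a warning is issued below 60 s).
* SSD component polarity is fixed by the max-positive-weight filter
  convention; when the noise covariance is nearly collinear with the source
  topography the convention can still flip polarity, and with it the BSI
  sign (observed in roughly 1 run in 20 of the sign-recovery benchmark).
* The segment cap of 90 s cannot be honoured for traces longer than
  5 × 90 s; the cap is then dropped with a warning.
* Peak re-detection per component falls back to the channel-average peak
  when a component shows no prominent maximum of its own.
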