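# Methods

## The measurement problem

During resonance-frequency breathing (~0.1 Hz), respiratory sinus arrhythmia
(RSA) and the baroreflex/Mayer rhythm merge into a single large heart-rate
oscillation. The package quantifies that state three ways: in the time
domain (RMSError of oscillation-cycle durations against the 10 s pacing
target), in the frequency domain (dominant PSD peak location, height and
mid-peak-height width), and comparatively across phases (the P₀.₁ index,
guided-phase maximal peak height over summed spontaneous-phase peak
heights in 0.04–0.4 Hz).

## Pipeline conventions

**Beat series.** Beat times are seconds from recording start; interval
`rr_ms[k]` is attributed to its starting beat. Artifact screening flags
intervals deviating more than 20% (configurable) from the median of the
five nearest intervals (the index-distance window {k−3…k+2}\{k}); an
ectopic pair (0.6× early beat, 1.4× compensatory pause) deviates 40% and is
caught on both intervals. Flagged intervals are replaced by linear
interpolation between valid neighbours — the minimal reading of replacement
"with interpolated adjacent values" — and beat times are rebuilt
cumulatively. A warning is emitted past 2% corrections, the usual quality
guideline for HRV recordings.

**Tachogram.** Cubic-spline interpolation of (interval start time, RR) on a
uniform 4 Hz grid, evaluated only inside the data span. 4 Hz comfortably
oversamples the 0.04–0.4 Hz analysis band.

**Detrending.** The smoothness-priors filter removes the trend estimate
`(I + λ²D₂ᵀD₂)⁻¹ z` from the mean-removed tachogram z (D₂ = second
difference, free boundaries; λ default 300). The pentadiagonal SPD system is
solved with a banded Cholesky factorization in O(n); tests verify the banded
route against a dense solve to 1e−8. The mean is not restored — spectral
analysis needs only fluctuations. The filter's "cutting frequency" is
defined as the −3 dB point of the high-pass magnitude response
`I − (I + λ²D₂ᵀD₂)⁻¹`, measured at the mid-record row against complex
exponentials (boundary effects die out a few hundred samples in; responses
at n = 1024 and 4096 agree to <1%). Away from boundaries this equals the
stationary response `λ²·16·sin⁴(πf/fs) / (1 + λ²·16·sin⁴(πf/fs))`. The
convention reproduces the widely used λ = 500 ↔ 0.035 Hz correspondence at
4 Hz; λ = 300 gives 0.046 Hz.

**PSD.** Single-segment periodogram of the full record with a Hann window
and density scaling (power per Hz), zero-padded to the next power of two
≥ 4× the record length. A single segment is deliberate: Welch averaging
would broaden the very resonance line under study. Density scaling makes
phases of different duration (8-min video, 5-min guided) comparable.
`PSDResult` carries two grids: the padded grid, used to *locate* the main
peak precisely (parabolic refinement over the three bins around the maximal
bin; height read at the raw bin so heights are comparable at fixed df), and
the native-resolution grid (no padding), used to *count* peaks. The split is
necessary: on an oversampled grid every window sidelobe is a strict local
maximum, whereas at the record's natural Fourier resolution an on-bin
sinusoid has exactly one. The peak census (the P₀.₁ denominator) takes all
strict local maxima in band with no prominence threshold (an option exists,
default off), excluding band-edge bins and maxima below 1e−10 of the band
maximum (FFT round-off). MPHW is the width at half the peak height, each
flank crossing found by linear interpolation.

Because the numerator of P₀.₁ is read on the padded grid and the
denominator on the native grid, the numerator can carry up to the Hann
scalloping gain (~1.4 dB) relative to a native-bin reading. The bias is
identical across records and conditions and cancels from every comparison
the package makes.

**Cycles.** Respiratory cycles are peak-to-peak delays of the 1 Hz resampled
belt signal (end of each inspiration); HRV cycles are crest-to-crest
intervals of the detrended tachogram. Peaks need a minimum separation
(3 s respiration, 5 s HRV — safely below the 10 s target) and prominence
≥ 25% of the signal's interquartile range; peak times are refined to
sub-sample precision by parabolic interpolation (without it, 1 Hz sampling
quantizes a 10 s breath into alternating 9 s / 11 s cycles). A respiratory
record is excluded — by raised signal, never silently — when its detected
cycle count deviates more than 30% from the count expected at 0.1 Hz; this
operationalizes the exclusion of low-SNR chest-belt records. RMSError is
computed over all retained cycles; a trim option can drop leading/trailing
transients (default 0).

**Device rule.** The guidance waveform is a 10 s triangle (rising 0→1 over
5 s, falling back over 5 s). The biofeedback verdict tests beat-wise heart
rate (60000/RR, one value per interval at its starting beat) for monotone
rise during inspiration and fall during expiration; a 0.1 bpm equality
tolerance absorbs float ties, and phases with fewer than two beats are
flagged indeterminate rather than judged. This per-phase monotonicity check
is the whole of the device's smoothness comparison; colour rendering is out
of scope.

**Group statistics.** Outliers are winsorized to the Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) with linear-interpolation quartiles;
winsorization preserves n. (At n = 4 the quartiles interpolate into the
extreme order statistics and the operation is not idempotent; it is for
n ≥ 5.) Shapiro–Wilk and Levene (centre = mean) are reported but never gate
the ANOVA. Post hocs are pooled-variance t tests with Holm step-down
adjustment (Welch by flag). The Bayes factor is the two-sample JZS default
(Cauchy prior scale √2/2 on the standardized effect), computed by adaptive
quadrature of the non-central-t marginal likelihood over the prior, as
log(BF10); a full multi-group Bayesian ANOVA is out of scope.

## The synthetic-physiology generator

RR intervals are modulated directly:

    RR(t) = mean_rr + rsa_amp·sin(2πφ(t)) + mayer_amp·sin(2πf_m t + φ₀) + noise

with beats placed iteratively (t_{k+1} = t_k + RR(t_k)/1000). Direct
interval modulation, rather than an integral-pulse-frequency model, is
sufficient for the spectral and cycle-duration properties under test. The
breathing phase φ integrates an instantaneous frequency that performs a
seeded mean-reverting AR(1) walk around the target (stationary SD =
`breath_jitter_sd_hz`, clipped at ±3 SD) — the model of human tracking
error. Its mean-reversion time constant is 2.5 s: pacer-following is
corrective within half a 5-s breathing phase, which keeps the realized
dominant frequency pinned at the pacing target (per-record peak-location SD
≈ 0.001 Hz, the dispersion real guided cohorts show) while spreading power
into the peak's width. A slower constant would let the dominant frequency
itself wander by several mHz, which guided subjects do not do. The
chest-belt signal shares φ exactly, plus additive noise.

Phase presets are the study conditions: guided 300 s at 0.1 Hz (RSA 60 ms,
jitter SD 0.005 Hz, beat noise 5 ms; the Mayer term is absorbed into the
resonant line), spontaneous 480 s at ~0.25 Hz (RSA 35 ms, jitter 0.015 Hz,
independent 25 ms Mayer wave at 0.1 Hz, noise 8 ms) around a 850 ms mean
RR. Amplitude invariants (`rsa + mayer + 4·noise < mean_rr`, noise clipped
at ±4 SD) guarantee positive intervals. Ectopic injection scales interval k
by 0.6 and k+1 by 1.4 (canonical extrasystole + compensatory pause,
configurable), preserving the pair's total time; event counts are Poisson
with ≥3-interval separation.

Cohorts draw per-subject traits (mean RR ~ N(850, 60) ms, spontaneous RSA
~ N(35, 6) ms and breathing rate ~ N(0.25, 0.03) Hz, all independent of
condition) and condition-level guidance quality: guided-phase jitter SD
0.013 / 0.008 / 0.005 Hz and RSA amplitude 48 / 58 / 62 ms for visual /
haptic / visuo-haptic, with the haptic group given the largest
between-subject amplitude spread (sensitivity to haptic stimuli varies more
across people). These parameters are calibrated so the qualitative findings
of guided-breathing studies emerge — visuo-haptic P₀.₁ roughly two-fold
above visual, RMSError ordered the other way — not to reproduce any
particular cohort's absolute group means, which depend on estimator
choices. All randomness flows from one seed through named per-stream
generators; cohorts are reproducible beat-for-beat.

**What the generator does not emulate:** baroreflex feedback (resonance
amplitude gain is imposed per condition, not emergent), cardiorespiratory
coupling beyond additive RSA, raw ECG/PPG waveforms, non-stationary drift
of mean heart rate, and motion artifacts other than the stereotyped ectopic
pair. Passing tests therefore show the *measurement chain* is correct under
controlled physiology-like input, not that the physiological effect itself
is real.

## Numerical and degenerate-input choices

* λ = 0 detrending returns identically zero (trend = signal), the limit of
  the normal equations.
* Peak refinement falls back to the raw bin when the three-point parabola
  degenerates; refinement offsets are clamped to ±½ bin for cycle peaks.
* A monotone density in the searched band raises a no-peak signal; an empty
  video-phase peak list makes P₀.₁ an explicit undefined-score error, never
  0 or ∞. P₀.₁ > 1 is possible (guided peak taller than summed video
  peaks) and is reported as-is with a flag.
* Zero within-group variance with equal means is a degenerate ANOVA signal;
  with unequal means F = ∞, p = 0.
* Per-participant pipeline failures become excluded rows with a reason; one
  bad record never aborts a cohort.

## Problem sizes

Simulation-based tests use 5-min guided / 8-min video records (the protocol
phase durations), cohorts of 8–20 per condition, 500 replicates for the
null-calibration of the ANOVA's type-I error, and 30 seeded replicates for
the group-mean peak-location checks — the scale of a real guided-breathing
cohort.

## Known limitations

* The P₀.₁ absolute scale depends on estimator settings (window, padding,
  density scaling); only comparisons under identical settings are
  meaningful, and the constructor enforces matched settings across phases.
* The artifact detector is tuned for isolated ectopic pairs; long artifact
  bursts (> 3 consecutive corrupted intervals) can escape the local-median
  window.
* The respiration SNR guard assumes the 0.1 Hz pacing target; spontaneous
  breathing records need the expected frequency passed explicitly.
* Whether reported peak "heights" are densities (per Hz) or integrated
  band powers is a genuine convention fork; the package exposes densities
  and documents the choice rather than guessing an integration rule.
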