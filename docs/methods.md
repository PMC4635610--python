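# Methods

## Model and assumptions

An ERP sample is an N × (K·L) matrix of single-trial row vectors (K channels
× L time samples, channel-major). The statistical model behind the
discriminant and the T² test is two multivariate normal populations with a
common covariance matrix; the pipeline's job is to bring the dimensionality
down to where that model is estimable from a few hundred trials. Every
reduction stage is a linear map, which is what makes the final discriminant
representable in all three spaces (selected principal components, frequency
coefficients, time-domain waveform) with identical decision values.

The frequency stage assumes the discriminative signal lives below the cutoff
frequency f_c = 1/S_c; components between f_c and 2f_c are retained but
attenuated linearly to smooth the cutoff. The wavelet stage assumes ERP
components are transient, roughly Mexican-Hat-shaped deflections, so that a
two-parameter (scale, latency) family captures them with far fewer
coefficients than the full time-frequency plane; the log-grid exploits the
natural scale invariance of this family (R grid lines per octave, R time
points per scale length).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `s_c` | cutoff scale (s); f_c = 1/s_c | 0.04 | 25 Hz low-pass, standard for late ERP components |
| `grid_rate` R | log-grid sampling rate (points per scale) | 15 | resolves component latency to ~s/15 without inflating N_G |
| `t_in`, `t_out` | Tukey fade-in duration / fade-out start (s) | 0.02 / 0.2 | suppress window-edge leakage |
| `pca_criterion` | retained variance P_v (%) or `"average"` | 99.0 | keeps virtually all signal variance while removing rank-deficient directions |
| `group_pca_criterion` | criterion for pooled-group fits | `"average"` | emphasizes shared group structure over idiosyncratic components |
| `c_individual`, `c_group` | outlier threshold coefficients | 2.7 / 2.5 | ≈ 3-SD flags under the approximately normal distance distribution |
| `dataset_limit` | flagged-trial fraction that discards a dataset | 0.5 | a dataset losing half its trials is unusable |
| `alpha_sd` | step-down selection level | 0.3 | deliberately liberal: missing a discriminative component costs more than carrying a noise one |
| `priors` | (p_A, p_B) class priors | equal | set to (0.136, 0.864) for a known oddball ratio |
| `holdout_stride` | classify every n-th trial in hold-out | 1 | raise to trade precision for time |

## Numerical choices

- **DFT basis.** Columns are DC then (cos, sin) pairs at f_j = j/T, each
  normalized to unit Euclidean norm over the L samples, so the reduced basis
  is exactly orthonormal and the inverse rotation is the transpose. The
  construction requires 2·f_c·T < L/2 (cutoff below Nyquist) and an integral
  sample count R0·T.
- **Tukey window.** The time envelope rises as ½(1−cos(πt/T_in)) on
  [0, T_in), is 1 on [T_in, T_out), and falls as ½(1−cos(π(T−t)/(T−T_out)))
  on [T_out, T). `t_out` is the *start* of the fade-out, not its duration —
  a convention to keep in mind when porting parameter files.
- **PCA.** Eigenpairs come from an economy SVD of the centered data
  (equivalent to the covariance eigendecomposition, O(n²d) instead of O(d³)
  for the usual n ≪ d case); components below 1e−12 of the top eigenvalue
  are discarded before any retention criterion. Covariances use the unbiased
  (n−1) denominator throughout. Principal-component *projections* are
  applied without mean subtraction, keeping the whole chain strictly linear.
- **Outlier iteration.** The retained component count Q_p is frozen once it
  repeats in two consecutive iterations; if the flagged count fails to grow,
  the previous iteration's flags are re-marked (anti-oscillation) and the
  dataset-level rule is evaluated; the loop stops when the flag set repeats,
  with a hard cap (`max_iter`, default 100) and a convergence warning on
  partial results. Flag comparisons use strict `>`. The per-condition pass
  freezes the principal axes and the component count from the whole-sample
  fit and re-estimates only the per-component variances and the mean within
  each condition's accepted trials ("no PCA" read as: no re-diagonalization).
- **Log-grid.** Scales are anchored at S0 = S_c/2 (the minimal scale is a
  grid line) and enumerated while s ≤ 4T, inclusive at both edges with a
  1e−12 relative tolerance; each line holds h = 0..⌊R·T/s⌋ time points. The
  convolution integral is a left-endpoint Riemann sum over [0, T) at the
  original sampling rate. Other anchorings (top-anchored, sample-quantized
  scales) change the vertex count by a fraction of a percent; the count is
  therefore a convention, not an invariant, and resource estimates use this
  package's convention.
- **Extrema.** The neighborhood of a vertex on the irregular grid is its two
  within-line neighbors plus the nearest-in-time vertex on each adjacent
  scale line; edges compare one-sided. Extrema are strict, with ties broken
  toward the lexicographically smallest (line, offset) index so exactly one
  vertex per flat plateau survives — reproducible feature sets at the cost
  of admitting plateau representatives. No minimum |t| is imposed; the
  step-down stage prunes noise features.
- **Step-down selection.** Components are two-sample t-tested in decreasing
  eigenvalue order at level α_sd and every significant one is kept (at least
  the first always, so the discriminant exists). Screening rather than
  stopping at the first acceptance is deliberate: in ERP feature spaces the
  top-variance components are typically spatially shared noise modes while
  the condition difference concentrates mid-spectrum, and a stop-at-first
  rule collapses the discriminant to the leading (usually uninformative)
  component. The SPC count is additionally capped at (smaller class size −
  2) so the pooled covariance stays invertible.
- **Decision rule.** Exact ties on the separation plane go to condition B,
  deterministically. Hotelling's T² converts to an F(p, n−p−1) tail
  p-value; calling it without `features_independent=True` emits a warning,
  because selecting features on the tested sample invalidates the null
  distribution.

## The synthetic generator

`SynthSpec` emulates a passive auditory oddball study: 9 channels at 500 Hz,
700 ms epochs starting 100 ms pre-trigger, 242 standard + 38 deviant trials
per dataset (priors 86.4% / 13.6%). The deviant−standard difference is a sum
of Mexican-Hat deflections — mismatch negativity (−3 µV, 200 ms,
fronto-central), P3 (+5 µV, 300 ms, parietal), negative slow wave (−2.5 µV,
400 ms, central) — on top of an obligatory −3 µV response at 100 ms common
to both conditions. Noise is spectrally synthesized 1/f (8 µV RMS) plus a
white floor (2 µV), with half the variance from a source shared across
channels: the spatial correlation is essential, because handling it is
precisely what the covariance-based machinery is for. Three trials per
dataset are scaled ×10 as artifact stand-ins; per-subject gains are
N(1, 0.2²). All draws derive from one mandatory seed.

What the generator does **not** emulate: rhythmic background (alpha
spindles), non-stationary noise, latency jitter across trials, volume-
conduction-realistic topographies, ocular artifacts. Passing tests therefore
show that the pipeline recovers transient, time-locked, spatially correlated
components from 1/f noise at realistic SNR — not that it is robust to every
failure mode of real recordings.

Under these conditions the pipeline lands where a well-functioning analysis
should: individual hold-out error ≈ 14% at equal priors (≈ 9% with oddball
priors against a 13.6% chance level), a few hundred to ~1500 scalogram
extrema reduced to a handful of selected components, and exact recovery of
the planted artifact trials at C = 2.5.

## Localization precision of scalogram extrema

The planted-recovery check compares detected extrema against each
component's *expected* scalogram location: the CWT of the known noiseless
difference curve divided by the per-vertex noise SD (estimated from an
independent signal-free draw). The division matters — 1/f noise power grows
with scale, so the t surface peaks at smaller scales than the raw response
does. Around that expected location the t surface forms a broad ridge along
the scale axis; with 38 deviant trials the detected extremum jitters by a
few grid lines in scale (and ~1 step in time) across noise realizations. The
acceptance test pins the behaviour at a fixed seed; latency is the precisely
recovered coordinate, scale is identifiable only to within a fraction of an
octave at this trial count.

## Problem sizes used by the test-suite

Unit and property tests run on reduced problems (3 channels, 200 Hz, 400 ms
epochs, 80 trials; grids of a few hundred vertices) chosen so the whole
suite, including the full-scale acceptance checks (9 channels, 280 trials,
S_c = 40 ms, R = 15, hold-out at stride 4; 20-seed outlier recovery; 2000
Hotelling replicates), completes in a few minutes. Statistical-expectation
checks (e.g. biased ≤ hold-out error in the mean) aggregate over 20 seeds at
the reduced size.

## Known limitations

- The vertex count of the log-grid depends on the anchoring convention (see
  above); counts from other implementations can differ by ~0.1–4% even for
  identical (S_c, T, R).
- Hold-out refits everything downstream of the whole-sample outlier stage
  per fold; the whole-sample PCA projection itself is fitted once on all
  trials, so the hold-out estimate is *almost* unbiased, exactly as the
  protocol prescribes.
- `classify` on raw trials requires the caller to apply the same windowing/
  baselining used in training; the pipeline object handles this, the
  low-level API does not.
- The iterative outlier procedure has no optimality guarantee; its
  convergence is enforced by the anti-oscillation rule and the iteration
  cap, and a small false-positive rate (~0.5–1% of trials at C = 2.5–2.7)
  is inherent to its mean + C·SD threshold.
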