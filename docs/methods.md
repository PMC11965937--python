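# Methods

This note documents the models, estimators and numerical choices behind
`emgfatigue`, what the synthetic generator does and does not emulate,
and the design decisions taken where the methodology was genuinely open.

## Synthetic fatiguing-EMG model

Surface EMG during isometric contraction is modelled as band-limited
Gaussian noise — the standard stochastic description of the interference
pattern of many asynchronous motor-unit action-potential trains — with
two deterministic fatigue trends:

* **Spectral compression.** The target median frequency falls linearly
  from `mdf_start` (default 90 Hz) to `mdf_end` (60 Hz) over the trial.
  The carrier is synthesised by weighted overlap-add: 256-sample
  sqrt-Hann frames of white noise are multiplied in the frequency domain
  by a 4-pole Butterworth band-pass magnitude (width `bandwidth`,
  default 60 Hz).  Because the spectral *median* of such a band sits
  2–3 Hz above its nominal centre, the centre is steered by three
  fixed-point iterations per frame so the output median frequency tracks
  the target to well under one spectral bin.
* **Amplitude growth.** A per-sample gain ramps linearly from 1 to
  `rms_gain_end` (default 1.8), after normalising the carrier to unit
  RMS over its first two seconds.  All artifact amplitudes are therefore
  in units of the initial signal RMS.

Artifacts: a 50 Hz powerline sinusoid with random phase (amplitude 0.1),
a 0.3 Hz sinusoidal baseline drift (amplitude 0.5), and white sensor
noise (SD 0.2).  The sensor-noise level is the one generator default the
underlying study design left open; 0.2 × initial RMS is a realistic
baseline for surface recordings and was fixed once before any evaluation.

Trajectories are linear rather than exponential because only the sign
and monotonicity of the trends matter downstream.  Labels are defined
operationally: the earliest `label_fraction` (default 1/3) of each trial
is "easy", the latest third "difficult", the middle discarded — a
monotone proxy for the in-test perceived-effort rating.  Each subject
receives ±10% multiplicative jitter on the MDF endpoints and gain so
grouped cross-validation sees real between-subject variance.  The study
layout default is 10 subjects × 10 trials × 3 channels at 1000 Hz,
60 s per trial.

**What the generator does not emulate:** motor-unit recruitment and
firing statistics, action-potential shapes, electrode lift or motion
artifacts, force output, non-monotone fatigue dynamics, inter-channel
correlation (channels are independent draws).  Passing tests on this
model therefore demonstrate that the pipeline recovers spectral and
amplitude fatigue trends from nonstationary band-limited noise — not
that it attains any particular accuracy on human recordings, where
class overlap is far larger.

## Preprocessing

Butterworth band-pass of order 4, 20–450 Hz (the conventional sEMG band
at fs = 1000 Hz); IIR notch at 50 Hz with Q = 30; mean subtraction last,
so the output mean is exactly zero.  Both filters are applied
forward–backward (zero phase) with reflective padding to suppress edge
transients; linearity and 50 Hz band-power reduction are asserted by
tests.  No specification of the original filters was available, so these
are the field's defaults.

## EMD family

* Extrema: strict local extrema with plateaus resolved to their
  floor-midpoint sample.
* Envelopes: natural cubic splines through the maxima/minima, each knot
  set extended by mirroring two extrema beyond both ends (the standard
  cure for envelope end-swing).
* Sifting stops when the Cauchy criterion
  `SD = Σ(h_prev − h)² / Σ h_prev² < 0.2` is met **and** the IMF
  property (|#extrema − #zero-crossings| ≤ 1) holds, or after 100
  iterations.  Decomposition stops when the residual has fewer than
  three extrema or at `max_imfs = 13`.
* Ensemble variants share one noise bank of `ensemble_size` white-noise
  realizations drawn from the decomposition seed; the realizations are
  decomposed once so that `E_k(w_i)` is the k-th mode of the *same*
  realization at every stage.  Defaults: ensemble size 100 in
  production, 30 in tests and the acceptance script; noise strength
  ε = 0.2 of the signal SD.
* ICEEMDAN conventions: the local-mean operator is
  `M(y) = y − first_imf(y)` (full sifting), `β0 = ε·SD(x)/SD(E1(w_i))`
  per realization and `β_k = ε·SD(r_k)` thereafter.  Stagewise
  telescoping makes reconstruction exact (≈1e−16 relative) for EMD,
  CEEMDAN and ICEEMDAN.  EEMD reconstruction carries residual ensemble
  noise that shrinks as 1/√N — a property the tests exercise directly.
  CEEMD cancels it by complementary ±noise pairs.

No third-party EMD implementation is used anywhere; the decompositions
are validated by their own invariants (exact reconstruction, spectral
ordering of modes, two-tone separation, mode-mixing recovery under
noise assistance).

## Features

Windows of 1000 samples (1 s) with 50% overlap; only windows lying
wholly inside a labelled span produce rows.  Per window and per source
component (raw plus the first `k_keep` IMFs, default 5):

* MAV, VAR (population), RMS — exact formulas.
* Welch PSD: 256-sample Hann segments, 128 overlap, mean detrend,
  density scaling (Parseval-consistent).  MF is the power-weighted mean;
  MPF is the half-total-power point with linear interpolation between
  bins.
* Instantaneous series: Hann-tapered 256-sample STFT frames at hop 64
  (no edge padding); per frame the mean frequency (**IMDF**) and median
  frequency (**IMNF**), summarised by their time-mean and least-squares
  slope.  *Naming caveat*: part of the sEMG literature attaches these
  two acronyms the other way round; this package consistently uses
  IMDF = instantaneous **mean** frequency, IMNF = instantaneous
  **median** frequency.
* Sample entropy with m = 2, r = 0.2·SD (field defaults); template
  counting is exact (no approximation), self-matches excluded, and an
  undefined entropy (zero match count) is surfaced as NaN in the table
  rather than silently zeroed.
* Hurst exponent by rescaled-range analysis over ≥8 log-spaced block
  sizes from 16 to n/4, with the Anis–Lloyd–Peters finite-sample
  correction: `H = 0.5 + slope(log(R/S) − log E[R/S])`.  Uncorrected
  R/S is biased to ≈0.58 for white noise at these lengths and would not
  recover H = 0.5; the corrected estimator recovers H = 0.5 within
  ±0.03 and H = 0.8 within ≈0.07 (a small residual downward bias at
  n = 4096 is inherent to R/S and documented by the tests' tolerances).

## t-SNE

Exact O(n²) implementation: per-point Gaussian bandwidths are bisected
until the conditional distribution's perplexity matches the target
within 1e−4 bits; joint affinities `p_ij = (p_{j|i}+p_{i|j})/2n`;
Student-t kernel with one degree of freedom in the embedding space; KL
divergence minimised by momentum gradient descent with the canonical
schedule (early exaggeration ×12 for the first 250 of 1000 iterations,
momentum 0.5 → 0.8, learning rate 200, per-parameter gains, seeded
Gaussian initialisation at SD 1e−4).  One addition: an uphill step after
the exaggeration phase triggers an adaptive restart (the step is
rejected and the momentum buffer cleared), which makes the recorded cost
trace monotone without changing where the optimiser converges.  Features
are z-scored per column before embedding because the Gaussian kernel
uses unscaled Euclidean distance.  Perplexity defaults to 30 with a
floor of (n−1)/3 for tiny inputs.  Degenerate all-duplicate inputs are
jittered with a warning.

## Classification and evaluation

SVM (RBF, C = 10, bandwidth `gamma="scale"`), KNN (k = 5,
distance-weighted votes, which also breaks ties toward the nearer
neighbour), and a one-hidden-layer (32-unit) perceptron with early
stopping and learning rate 0.01 (the default 0.001 underfits small
feature tables within the early-stopping window).  Feature imputation
(median) and z-scoring are fitted on train folds only.

Two protocols are first-class because the honest choice was genuinely
open: stratified k-fold over windows (matches common practice; inflated
by trial autocorrelation) and grouped-by-subject k-fold (no subject
spans train and test).  The t-SNE representation is transductive — the
embedding sees all windows before the split — so every report produced
from it carries an explicit `leakage_caveat`.

The IMF-count sweep is evaluated under grouped-by-subject CV in the
acceptance script: at desk scale the synthetic classes are separable
enough that window-level CV saturates at 100% for every k, leaving no
trend to measure, while the grouped protocol leaves headroom and shows
the expected monotone gain from adding IMF features.

## Problem sizes

Tests and the acceptance script run deliberately small configurations —
typically 4 subjects × 2 trials × 1 channel at 20 s per trial with
ensemble size 30, and 2 × 2 × 1 at 15 s for the five-way method
comparison — chosen so the full suite completes quickly on one core
while every statistical assertion retains comfortable margins (the
separations involved are many standard errors wide).  The generator's
*defaults* remain the full study layout; nothing in the library depends
on the reduced sizes.

## Known limitations

* The synthetic task is far easier than human data: near-ceiling
  accuracies here say nothing about attainable accuracy on real
  recordings.
* ICEEMDAN mode counts can differ by 1–2 between realizations of the
  same process; downstream code indexes modes positionally (imf1 …
  imf_k), which is the convention but blurs comparisons across methods
  when counts differ.
* R/S Hurst estimates on 1000-sample windows are noisy (SD ≈ 0.08);
  they add discriminative value in aggregate but are not reliable
  per-window estimates.
* The exact t-SNE is O(n²) in memory and time; beyond ~10⁴ windows a
  Barnes–Hut implementation would be needed.
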