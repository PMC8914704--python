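# Methods

This note documents the models, defaults and numerical choices behind
`neuroictal`, and what the synthetic validation does and does not
establish.

## Data model and epoching

A session is a `[n_channels × n_samples]` microvolt array at a fixed
sampling rate with labelled intervals.  Times are seconds, intervals
half-open `[start, end)`, sample indices 0-based.  Epoching advances by
`epoch_s · (1 − overlap)` and drops the trailing partial window.

**Epoch labelling at seizure boundaries.** Annotations mark intervals,
not epochs, and an epoch can straddle an onset.  We label an epoch
ictal when ≥ 50 % of its span overlaps a seizure interval (threshold
configurable).  This is a symmetric, unbiased default; discarding
boundary epochs or any-overlap labelling are reasonable alternatives a
user can emulate by changing the threshold.

**EDF.** The reader parses standard 16-bit EDF, converts to microvolts
via the physical/digital calibration (rejecting channels with a
degenerate calibration, since uncalibrated digital values would make
feature magnitudes incomparable across sessions), and reads EDF+
annotation channels (events whose text contains "seiz" become seizure
intervals).  A sidecar CSV (`start_s,end_s,label`) always takes
precedence.  A minimal writer exists for round-trip tests and fixtures.

## Wavelet transform

No wavelet library is assumed; the six-level decomposition is an
orthogonal Daubechies-4 filter bank implemented directly.  The signal is
reflection-padded on the right to a multiple of 2⁶ and each level
applies *circular* convolution (a periodized transform).  Because the
analysis operator is then exactly orthogonal, synthesis is its
transpose and reconstruction is exact to machine precision; the padding
is cropped after reconstruction.  Coefficient counts are `n_pad / 2^k`
per level — slightly different from symmetric-extension conventions,
which matters only if coefficients are compared across implementations.

Cleaning soft-thresholds all detail bands at the universal threshold
σ√(2 ln N) with σ = MAD(D1)/0.6745, and removes the mean of A6
(low-frequency drift).  Thresholding attenuates coefficients rather
than discarding epochs; epoch rejection can be layered on top by the
caller if hard artifact gating is wanted.

## Sample entropy

`SampEn(m, r) = −ln(A/B)` with Richman–Moorman counting: both template
lengths use the same `n − m` start positions, matches use the Chebyshev
metric, self-matches are excluded.  Defaults: `m = 2` (appropriate for
short series), `r = 0.2 · SD` per channel (field convention; the
tolerance is configurable and may be absolute).  Degenerate cases are
explicit: constant series with relative tolerance raise (r would be 0);
`A = 0` returns +inf (no length-m+1 matches: maximal irregularity);
`B = 0` raises (the conditional probability is undefined).  Counting is
done with KD-trees and is exactly equal to brute-force enumeration (a
property the tests assert to 1e−10).

## Correlation dimension

Grassberger–Procaccia: delay-embed with dimension `E = 5` and delay τ =
first zero-crossing of the autocorrelation (capped at 50 samples ≈
fs/10 at 500 Hz); compute the correlation sum C(r) over pairs separated
in time by more than τ (Theiler window) on 24 log-spaced radii between
the 1st and 50th percentile of pairwise distances; the estimate is the
slope of log C vs log r over the best sliding window of 8 consecutive
radii, judged by linear-fit R², restricted to radii with C(r) > 0.
Windows on which C(r) is constant (saturated) carry no scaling
information and are skipped.  Distances are Euclidean by default
(Chebyshev available).

Exactly periodic noise-free signals sampled commensurately (e.g. a
10 Hz sine at 500 Hz) collapse onto finitely many embedded points and
have no scaling region; any noise or incommensurate frequency restores
the expected dimension (≈ 1 for a limit cycle).

## Quantization

Per-feature affine map of the *training* range `[min, max]` to
`[0, 255]`, rounded half-up (the midpoint maps to 128), applied
identically at train and test time with clipping; constant features map
to 0, non-finite values saturate at 255.  21 channels × 12 features =
252 bytes, inside the 256-byte hardware pattern budget.

## RCE network

Training rules (per presented vector v with label y):

1. every opposite-class prototype p with d(v, p) ≤ radius(p) shrinks to
   `max(min_if, d − 1)` — the smallest exclusion step in the integer L1
   byte metric;
2. if no same-class prototype covers v, commit v with radius
   `clamp(min_d_opposite − 1, min_if, max_if)` (max_if when no opposite
   prototype exists), capacity permitting (overflow drops the vector
   with a warning, as the hardware does — no eviction).

Passes over the full training set (seizure vectors first, mirroring the
k-NN presentation order; order shapes the decision space) repeat until
a pass changes nothing.  Identical vectors with conflicting labels both
persist at `min_if`; classification then resolves by nearest distance
with ties broken toward seizure — the sensitivity-first choice for a
tracer-injection trigger, applied consistently in k-NN voting too.

Defaults: `min_if = 2`, `max_if = 0.4 · (255 · n_features)`, both
configurable; neither register has a canonical published value.  With
`k > 1` the vote is taken among the k nearest *firing* prototypes.

## Two-stage systems

The individual (per-patient) primary classifier handles what it is sure
of; Unknowns (RCE) or predictions with probability < 0.8 (SVM/MLP) go
to a population-trained 1-NN second stage that has never seen the test
subject.  The SVM's probabilities come from scikit-learn's internal
cross-validated Platt calibration.  Alternative Unknown resolutions
(assign-to-seizure, assign-to-normal) are provided for comparison;
assigning Unknowns to seizure can only raise sensitivity and lower
specificity, a monotonicity the tests assert.

## Synthetic cohort

The generator encodes the *feature-level* claims made about focal
seizures, not the biophysics of any real dataset:

- **Background** (all channels): band-limited Gaussian noise in the
  delta/theta/alpha/beta bands (per-subject RMS gains drawn from
  8–16 / 4–9 / 6–14 / 2–5 µV) plus 1/f noise (6–12 µV).  Nothing above
  the beta band ⇒ smooth ⇒ low SampEn; stochastic ⇒ the CD estimate
  saturates high (≈ 4 at E = 5).
- **Ictal discharge** (a focal subset of 4–8 channels): spike-and-wave
  at 2.5–4 Hz whose cycle amplitudes follow a logistic map
  (r ∈ [3.75, 3.99]), plus a sample-level logistic-map ripple band-passed
  to 15–45 Hz by a *short FIR* filter.  The FIR choice is deliberate:
  the filtered value is a function of a short window of the orbit, so
  the ripple stays low-dimensional (an IIR filter's long memory would
  inflate the attractor dimension), while its mid-band irregularity
  both survives wavelet thresholding and breaks SampEn template
  matches.  Ictal RMS is 2.5–4× background; background is attenuated
  ×0.1 under the discharge, with 1 s cosine on/off tapers.
- **Sessions**: 600 s background + 71 s seizure by default (the
  seizure duration matches the reported per-session average; the
  background is desk-scale minutes rather than clinical hours), onset
  uniform in [0.3, 0.7] of the background span.  Everything is
  deterministic in the master seed; a session is bitwise-reproducible
  from (profile, spec).

What a green validation establishes: the pipeline separates classes
whose nonlinear-feature contrast has the documented direction, under
focal channel involvement and strong inter-subject variability.  What
it does not establish: clinical performance.  Real EEG has artifacts
(ocular, muscle, electrode), non-stationary background, seizure
evolution and propagation, none of which are modelled; the generator's
separability is by construction stronger than clinical reality.

## Evaluation

Sensitivity = TP/(TP+FN)·100 (the sensitivity denominator is sometimes
misprinted as TP+TN; the prose definition — fraction of seizure
examples detected — forces TP+FN, which is what we implement and test),
specificity = TN/(TN+FP)·100, precision, recall, F1.  Zero-denominator
metrics are `None`, excluded from cross-subject means and counted.
Cross-subject dispersion is the population variance (ddof = 0).
Training sets are rebalanced to 3 normal vectors per seizure vector
(seeded, without replacement); test sessions are evaluated whole.
When m > 1 sessions are held out, split enumeration is capped at 50
random combinations per subject (configurable; full enumeration
available).

## Desk-scale performance defaults

Two caps keep feature extraction tractable on one CPU
(≈ 10 ms/epoch-channel): SampEn uses at most the first 1250 samples of
an epoch-channel and the CD embedding is subsampled to at most 400
points (seeded *random* subsampling — an even stride would alias
periodic orbits into clusters and bias the dimension down).  Both are
`SampEnParams`/`CDParams` fields and can be raised for fidelity.

## Known limitations

- The periodized wavelet boundary handling differs from common
  symmetric-extension conventions (coefficient values near epoch edges
  differ; band energies are nearly identical).
- CD estimates at 400 embedded points resolve dimensions up to ≈ 5;
  contrasts, not absolute dimensions, are meaningful.
- The EDF reader handles the common single-rate, 16-bit case only.
- Population-mode results on the default cohort are intentionally poor
  (profiles are drawn independently per subject); they demonstrate the
  individual-vs-population contrast, not a realistic population model.
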