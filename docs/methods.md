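# Methods

This note documents the models, estimators, and design choices behind
`pcgkit`, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic benchmark does and
does not demonstrate.

## Signal model and preprocessing

A phonocardiogram is treated as a mono, dimensionless-amplitude time series.
Every recording is resampled to a canonical 8000 Hz with polyphase
band-limited resampling (Kaiser-windowed low-pass, β = 12; plain decimation
is never used because aliasing would fold energy into the murmur bands) and
z-score normalized, `x_new = (x − μ)/σ`. The standard deviation uses the
sample (N−1) convention by default — the default of mainstream numerics
environments — switchable to the population form via the `ddof` argument.
Normalization is applied in both the feature path and the scalogram path by
default and can be disabled per pipeline config (`normalize: false`). Note
that with normalization on, the `mean`, `std`, and `rms` features are fixed
at ≈0/1/≈1 by construction and carry no class information; disabling
normalization restores them as genuine amplitude features.

## Synthetic phonocardiograms

The simulator is phenomenological: it reproduces the time-frequency
signature of auscultation findings, not hemodynamics.

* **S1 / S2** are Gaussian-windowed tone bursts (σ = duration/6, truncated
  at ±3σ): S1 at 45 Hz, 0.12 s; S2 at 90 Hz, 0.09 s, onset at 35% of the
  cycle. Default heart rate 75 bpm.
* **Murmurs** are band-passed white noise (4th-order zero-phase Butterworth)
  shaped by a window-relative envelope:
  * AS — systolic ejection murmur, 100–400 Hz, diamond
    (crescendo–decrescendo) envelope, cycle fraction 0.10–0.33;
  * MR — holosystolic plateau murmur, 100–300 Hz, 0.04–0.37;
  * MS — diastolic decrescendo rumble, 30–80 Hz, 0.55–0.95 (the classic
    low-pitched rumble sits below ~80 Hz, which also keeps the MS spectral
    centroid below Normal's);
  * MVP — mid-systolic click (20 ms, 300 Hz) plus a late-systolic crescendo
    murmur, 150–400 Hz, 0.24–0.36.
* **Noise**: additive white Gaussian at 25 dB SNR by default (`inf`
  disables it). Recordings default to 3 s — a few cardiac cycles, typical of
  short auscultation clips. Per-recording heart rate is jittered ±10% and
  murmur amplitude ±20% (documented constants), driven entirely by the
  recording's seed; dataset-level seeds are spawned deterministically from a
  master seed, so datasets are bit-reproducible.

What the simulator does *not* emulate: respiration and sensor-coupling
artifacts, heart-rate variability within a recording, pathological S1/S2
morphology changes, recording-chain coloration, and inter-patient
variability beyond the jitter above. The synthetic classes are separable by
design, so a high holdout accuracy on them validates pipeline correctness —
it says nothing about clinical discrimination on real recordings.

## Features

**Time domain (10).** RMS; shape factor RMS/mean|x|; skewness and kurtosis
as the third and fourth standardized moments with population (1/N)
normalization — kurtosis is the raw moment, so a Gaussian scores 3 (no −3
subtraction); peak = max|x|; impulse factor peak/mean|x|; crest factor
peak/RMS; clearance factor peak/(mean√|x|)²; mean; sample std. The identity
`crest = impulse / shape` holds algebraically and is tested.

**Spectral quality (3).** SNR, SINAD, and THD in dB are estimated from a
one-sided periodogram with a periodic Kaiser window (β = 38, chosen for its
very low sidelobes so leakage grouping stays local) and constant detrend.
The fundamental is the largest non-DC component; each component's bins
extend from its peak to the neighbouring spectral minima; harmonics are the
local peaks near the first 6 integer multiples of the fundamental (search
window ±f₀/4). Noise power is everything not assigned to DC, fundamental,
or harmonics. The estimator settings are documented defaults — the ratios
themselves are standard, but any concrete estimator must pick a window and a
harmonic count.

**MFCC (13).** 25 ms Hamming frames with 10 ms hop (the common
speech-processing default), power spectrum on a 256-point FFT, 26 triangular
filters equally spaced on the mel scale `mel(f) = 2595·log₁₀(1 + f/700)`
between 0 and 4000 Hz, natural log of the filter energies (floored at the
smallest positive double), orthonormal DCT-II, coefficients 0–12 retained
(the 0th, an overall log-energy, is kept by default; `include_zeroth=False`
switches to 1–13). The recording-level feature is the per-coefficient mean
over frames — the simplest aggregation that produces one fixed-length vector
per recording. A gain change g shifts only coefficient 0, by
`2·ln(g)·√(n_filters)`; coefficients 1–12 are gain-invariant.

## Feature selection

Continuous features enter a chi-square independence test through
equal-frequency (quantile) binning with 10 bins; empty/duplicate bins are
merged. The importance score is `−ln p`, with p floored at the smallest
positive double so scores stay finite; a constant feature gets p = 1,
score 0. Quantile binning makes scores invariant under strictly monotone
feature transforms and under permutation of the recordings. Degrees of
freedom follow the independence test, (bins−1)(classes−1), which is the
correct df for a feature-vs-class association table (a goodness-of-fit df of
classes−1 would apply only to a one-dimensional frequency comparison). The
top 15 features by score are kept; ties break by canonical feature order.
Selection is fitted on the training split only, never on held-out data.

## Weighted KNN

Features are z-scored with training-set statistics (a constant column gets
deviation 1 so standardization stays defined); distances are Euclidean in
that space, which stops large-magnitude features from dominating. Each of
the k nearest neighbours votes with weight 1/d; the reported per-class
shares are the normalized weight sums. Exact matches (d = 0) are decided by
majority among the zero-distance neighbours alone, which is the limit of
1/d voting. A tie in summed weights goes to the class appearing first among
the nearest neighbours (deterministic). Default k = 10 — a conventional
choice at a few hundred training points — exposed in the config together
with a stratified cross-validation helper (`cross_validate_k`). Evaluation
uses a stratified 80/20 holdout split, deterministic per seed. Brute-force
distance computation is the contract; at n ≤ a few thousand no tree
acceleration is warranted.

## Scalograms

The CWT uses the generalized Morse wavelet with symmetry γ = 3 and
time-bandwidth P² = 60 (hence β = P²/γ = 20), the de-facto default analytic
wavelet for time-frequency analysis, implemented as a frequency-domain
filter bank: `Psi(ω) ∝ ω^β·exp(−ω^γ)`, peak-normalized, evaluated at 12
voices per octave from the Nyquist frequency down to the lowest frequency
whose ±2σ time support fits the signal. Multiplication in the FFT domain
makes the transform exactly covariant under circular time shifts, which is
tested. Images are produced by per-image min–max scaling, quantization to a
fixed 128-level jet colormap, and bilinear resize to 224×224×3 — the input
contract of common ImageNet-family CNNs. Per-image (rather than global)
scaling and the colormap choice are the main arbitrary degrees of freedom in
any scalogram-image pipeline; both are fixed constants here, so exported
datasets are self-consistent within this toolkit. Magnitudes are not
log-scaled before colormapping.

## Metrics

The confusion matrix is ordered (AS, MR, MS, MVP, N). One-vs-rest collapse
gives TP/TN/FP/FN; accuracy, sensitivity, and specificity are the usual
ratios. The diagnostic F1 is the harmonic mean of **specificity and
sensitivity** — deliberate, because for a screening report both error
directions matter symmetrically — and is kept strictly separate from the
conventional precision–recall F1 (`precision_recall_f1`). Metrics are held
at full precision internally; display rounds half-up to 2 decimals (with a
12-decimal pre-quantization so binary float noise cannot flip a half-up
decision). Macro averages are unweighted means over the four disease
classes; the summary row of a printed report averages the displayed
(2-decimal) per-class values, matching how such tables are conventionally
assembled. A zero denominator yields NaN, an explicit undefined-metric flag.
Per-class metrics are integer-consistent by construction
(`accuracy·total = 100·(TP+TN)` exactly before rounding).

## Problem sizes and numerical choices

The validation suite exercises the end-to-end pipeline at 40 recordings per
class (200 total, 160/40 split) across 5 seeds, feature oracles on 100
random 400-sample signals against naive-loop references at 1e−9 relative
tolerance, and the WKNN voting rule against a brute-force oracle on 200
random instances. These sizes were chosen to exercise every code path with
comfortable statistical margins while keeping the default suite fast.

## Known limitations

* The simulator's separability means reported synthetic accuracies are an
  upper bound of pipeline health, not a clinical claim.
* SNR/SINAD/THD assume a tone-like fundamental; on broadband murmur signals
  they act as generic spectral-shape descriptors rather than distortion
  measures.
* The scalogram export fixes colormap and scaling; images from other
  scalogram tools are not pixel-comparable.
* No denoising or segmentation is performed; recordings are assumed
  reasonably clean and longer than one cardiac cycle.
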