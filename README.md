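# pcgkit — heart-sound classification toolkit

`pcgkit` is a Python toolkit for computer-aided diagnosis of heart valve
disease from phonocardiograms (PCG): audio recordings of heart sounds
captured at the chest wall. It classifies a recording into one of five
categories — normal (N), aortic stenosis (AS), mitral stenosis (MS), mitral
regurgitation (MR), and mitral valve prolapse (MVP) — without segmenting the
signal into S1/systole/S2/diastole. It is aimed at biomedical-signal
researchers and engineers who need a transparent, scriptable baseline
pipeline plus a CNN-ready scalogram exporter.

## What it does

* **I/O and normalization** — WAV in/out, channel averaging, band-limited
  polyphase resampling to 8000 Hz, and z-score normalization
  `x_new = (x − μ) / σ`.
* **Synthetic PCG simulator** — seeded, labeled five-class heart-sound
  recordings (Gaussian tone bursts for S1/S2, envelope-modulated band-passed
  noise for murmurs), so the entire pipeline is testable without clinical
  data.
* **26 hand-crafted features per recording** — 10 time-domain statistics
  (RMS, shape factor, skewness `m₃/m₂^{3/2}`, kurtosis `m₄/m₂²`, peak,
  impulse/crest/clearance factors, mean, std), 3 spectral-quality measures
  (SNR, SINAD, THD in dB from a Kaiser-windowed periodogram), and 13 MFCCs
  (mel scale `mel(f) = 2595·log₁₀(1 + f/700)`, Hamming frames, triangular
  filterbank, orthonormal DCT-II, per-coefficient mean over frames).
* **Chi-square feature selection** — quantile-binned feature-vs-class
  contingency tables; importance score `−ln p`; top 15 kept.
* **Weighted KNN** — Euclidean distances in standardized feature space; each
  of the k = 10 nearest neighbours votes with weight `1/d`.
* **Morse-wavelet CWT scalograms** — time-frequency images (γ = 3,
  time-bandwidth 60, 12 voices per octave) exported as 224×224×3 RGB PNGs in
  class folders for transfer-learning image classifiers.
* **Diagnostic metrics** — one-vs-rest accuracy, sensitivity, specificity,
  and the diagnostic F1 = `2·Spec·Sens/(Spec+Sens)` (harmonic mean of
  specificity and sensitivity; the conventional precision–recall F1 is
  available separately), with macro-averages over the four disease classes.

## Worked example

```bash
pcgkit simulate --n-per-class 20 --seed 7 --out demo/data
pcgkit evaluate --data demo/data --seed 7
```

prints (100 simulated recordings, stratified 80/20 holdout, top-15 features,
WKNN k = 10):

```
                AS     MR     MS    MVP      N  disease avg
accuracy     100.0  100.0  100.0  100.0  100.0        100.0
sensitivity  100.0  100.0  100.0  100.0  100.0        100.0
specificity  100.0  100.0  100.0  100.0  100.0        100.0
f1           100.0  100.0  100.0  100.0  100.0        100.0
overall accuracy: 100.00%
```

Rows are the one-vs-rest metrics per class in percent; `disease avg` is the
unweighted mean over AS/MR/MS/MVP (Normal excluded). The synthetic classes
are constructed to be separable, so a perfect holdout score on 20 held-out
recordings is the expected behaviour — it validates the pipeline wiring, not
clinical performance.

Train a model once and diagnose single recordings:

```bash
pcgkit train --data demo/data --model-out demo/model.json --seed 7
pcgkit diagnose demo/data/MS/MS_0003.wav --model demo/model.json
```

```
prediction: MS
    MS: 1.000
    AS: 0.000
    ...
```

The per-class values are normalized 1/d vote shares. Scalogram export for an
external CNN trainer:

```bash
pcgkit scalogram --data demo/data --out demo/images   # 224x224x3 PNGs per class
```

The same functionality is available as a library (`pcgkit.synth`,
`pcgkit.features`, `pcgkit.selection`, `pcgkit.wknn`, `pcgkit.scalogram`,
`pcgkit.evaluate`, `pcgkit.pipeline`).

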