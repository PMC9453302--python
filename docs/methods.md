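# Methods

## Signal model and simulator

Electrode data follow the instantaneous linear forward model
`X = A S + N`. Each latent source is a sum of narrow-band components —
white noise band-pass filtered to the band, normalized to unit RMS and
scaled by a per-band RMS amplitude in µV — plus a 1/f^γ background
(γ = 1 by default) synthesized by spectral shaping of white noise with
the DC bin zeroed. Filtered white noise is used rather than pure
sinusoids so each band has random phase and realistic bandwidth; no
biophysical head model, eye-blink or EMG artifacts are simulated.

Default bands (RMS µV, center Hz, bandwidth Hz):

| band  | sleepy class | normal class |
|-------|--------------|--------------|
| delta | 0.5, 2.5, 3  | 0.5, 2.5, 3  |
| theta | 0.5, 6, 4    | 0.5, 6, 4    |
| alpha | √3, 10.5, 5  | 1.0, 10.5, 5 |
| beta  | 1.0, 21.5, 17| √3, 21.5, 17 |

The √3 : 1 amplitude ratio gives a 3 : 1 alpha/beta band-power ratio for
the sleepy class and its mirror image for the alert class — the classic
drowsiness phenomenology. `power_ratio` is configurable.

The mixing matrix defaults to identity plus Gaussian off-diagonal
leakage (sd 0.1, seed-controlled): every channel predominantly sees one
source with mild cross-talk, the minimal structure the forward model
requires. Sensor noise is i.i.d. Gaussian (sd 1 µV). A per-subject
multiplicative gain `1 + 𝒩(0, 0.1)` (drawn once per subject, floored at
0.1) emulates inter-individual amplitude variation. The default protocol
is 20 subjects in two equal groups (sleep-deprived → sleepy label),
3 sessions × 420 s × 40 trials at 500 Hz on 8 generic channels
(ch1…ch8). Trials are realized downstream by windowed segmentation of
the continuous session rather than as discrete events.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so datasets are bit-reproducible
and independent of generation order.

## Preprocessing

- **Filter**: Butterworth band-pass 1–30 Hz applied forward–backward
  (`sosfiltfilt`, zero phase). Default order 5 — the smallest order whose
  two-pass magnitude response attenuates 50 Hz mains interference by
  more than 40 dB (measured ≈ 48 dB) while leaving the 10 Hz passband
  within 0.001 dB. Order and phase behaviour are configurable.
- **Segmentation**: half-open windows `[start, start + w)` in samples;
  default 2 s, no overlap → 210 epochs per 7-min session, near the
  40-trials-per-session granularity while giving enough training
  samples. Trailing samples that do not fill a window are dropped.
- **Normalization**: per-epoch, per-channel mean subtraction (zero-center).
- **Artifact rejection**: peak-amplitude threshold, default 100 µV, a
  standard surrogate for "only clean signals considered"; applied before
  augmentation only.

## Augmentation

New training epochs are `x′ = x ⊙ n` with `n ~ 𝒩(μ=1, σ)` drawn per
sample (default) or per channel. The density used is the standard normal
pdf with the conventional `2σ²` in the exponent. Defaults σ = 0.1 and
2 copies per epoch: a mild perturbation that preserves class structure
(`E[x′] = x`; in per-channel mode the normalized PSD is exactly
preserved). Augmentation always happens after splitting and only on the
training side; the CV harness asserts no augmented epoch reaches a test
fold. Additive noise schemes and geometric transforms are deliberately
excluded — they alter local features or destroy the time axis of EEG.

## Features

- **Band power**: Welch PSD (1 s Hann segments, 50 % overlap, density
  scaling) integrated over delta/theta/alpha/beta bands tiling the
  1–30 Hz passband; log-transformed by default (features are
  variance-like and right-skewed).
- **CSP**: per-epoch covariances are trace-normalized and averaged per
  class; `scipy.linalg.eigh(C_A, C_A + C_B + ridge)` yields eigenvalues
  in [0, 1] (class-A variance fractions; class-B values are their
  complements). Ridge regularization defaults to 1e-6 of the mean
  eigenvalue, keeping degenerate toys solvable. Filters are the top and
  bottom `n/2` eigenvectors (default n = 4); features are normalized
  log-variances of the filtered signals. The implementation is verified
  against an independent whitening-route eigendecomposition.

## Network

The primary variant (`compact_1d`) matches the data's true shape:
convolutions run along time across all channels. Kernels are 5, 3, 3
with ReLU after each, max-pool (2/2) after the first two, then two
fully-connected layers (default 32 units, then 2) and softmax. Default
widths 8/16/16 filters keep the parameter count small, consistent with
the design goal of few learnable parameters on little data.

A second variant (`transfer_table1`) transcribes an AlexNet-style stack
(96@11 stride 4 → LRN → pool 3/2 → 256@5 → LRN → pool → 384@3 → 384@3 →
256@3 → pool → FC 4096 × 2 → softmax) adapted to 1-D. Its published
description is internally inconsistent about input resolution
(two-dimensional image sizes versus 8-channel time series); the
implementation follows the data and treats this variant as a structural
reference and fine-tuning substrate rather than the primary model.

Training: mini-batch SGD, momentum 0.9, base learning rate 0.001, batch
32, ≤ 20 epochs, cross-entropy; inputs standardized per channel with
training-set statistics; He initialization. Early stopping with
patience 5 on validation loss; the best-validation-loss weights are
returned. One log row per validation pass records epoch, cumulative
iteration, elapsed time (HH:MM:SS), validation accuracy (%), validation
loss, and base learning rate. Fine-tuning plans freeze any layer prefix
(default: everything before the first fully-connected block); frozen
parameters are bit-identical before and after training, which the tests
assert. There being no public pretrained EEG weights for this stack,
"transfer" is realized as train → freeze → fine-tune within the package.
The whole engine is numpy; backprop is validated against central finite
differences for every parameterized layer type, including the
cross-channel (local response) normalization.

## Evaluation

Holdout splitting is stratified by class (the 20 % held-out side is
further halved into validation and test, seed-controlled, since the
protocol's "test and validation" fraction does not fix the boundary).
k-fold CV uses shuffled folds with a fixed random state; stratification
is on by default so per-fold class proportions stay within one epoch of
the global proportions (plain shuffled folds are available, and are used
automatically when k exceeds the smallest class count, e.g.
leave-one-out). Subject-aware splitting (`group_by_subject`) is off by
default but available for honest cross-subject generalization
experiments. Metrics are computed from first principles (confusion
counts, per-class precision/recall/F1 by swapping the positive class,
undefined precision reported as 0 with a flag); ROC via threshold sweep
with trapezoid AUC. Baselines are library-default decision tree, LDA
with automatic shrinkage, RBF-SVM, and 5-NN on standardized features,
evaluated under identical folds.

## Desk-scale benchmark sizes

The canned recovery experiment (`drowseeg.study`) simulates 20 subjects
× 1 session at 125 Hz with 2 s windows, yielding 2,000 epochs with the
default 3 : 1 alpha-power separation. 125 Hz keeps the full 1–30 Hz
analysis band (Nyquist 62.5 Hz) while making 10-fold CV of the CNN fast
on a single CPU; the generator's default remains 500 Hz. The
label-shuffled null control refits the SVM pipeline on shuffled labels
and evaluates a 200-epoch held-out test side.

## What passing tests do and do not show

The simulator separates classes *spectrally* under an identical mixing
matrix. Consequently band-power features are close to ideal here (CSP
picks up class differences only via variance profile, and is noticeably
weaker alone than on real cohorts where spatial topographies differ),
and near-ceiling accuracies are expected and observed. Passing therefore
demonstrates that the pipeline is wired correctly end to end — no label
leakage, augmentation confined to training folds, classifiers able to
recover known structure — not that comparable accuracy would be reached
on real recordings, which carry artifacts, non-stationarity,
inter-subject variability and far weaker class contrasts than the
simulation's clean 3 : 1 ratio.

## Numerical notes and limitations

- Filter edge transients: zero-phase filtering is applied to whole
  sessions before segmentation, so epochs never straddle filter edges.
- Degenerate inputs fail fast: flat epochs are rejected by CSP readout
  (log of zero variance), empty partitions and single-class folds raise,
  and an all-rejecting artifact threshold returns an empty set with a
  warning rather than an error.
- CSP sign is arbitrary per eigenvector; comparisons are made up to
  sign.
- Training-log elapsed time is wall clock; determinism guarantees cover
  every other column.
- The transfer variant is trainable but slow at 4096-unit widths on CPU;
  it exists for structural fidelity and freezing experiments.
- No ICA/regression artifact correction, re-referencing, filter-bank
  CSP, Riemannian features, or recurrent models — out of scope.
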