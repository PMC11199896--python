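# Methods

## Problem

Error-related potentials (ErrPs) are stereotyped EEG responses evoked when a
person perceives an error: a sharp fronto-central negativity (Ne) followed
by a positivity (Pe) within the first few hundred milliseconds after the
eliciting event. Detecting them on single trials enables error-aware
brain–computer interfaces, but single-trial ErrP classification is hard:
EEG is noisy and non-stationary, error trials are rare (roughly one in
five), and classifiers trained on one task or subject transfer poorly to
another. This package implements a general cross-task ErrP classification
method: a compact convolution + transformer-encoder network, trained with a
leakage-safe oversampling and cross-validation strategy, and transferred to
new tasks by pretraining on one paradigm and fine-tuning on another.

## Preprocessing

Inputs are reduced to a canonical representation of 2 channels × 64 samples
per trial:

1. **Bandpass** 1–10 Hz, 4th-order Butterworth. The filter is applied
   zero-phase (forward–backward, `sosfiltfilt`), which squares the
   magnitude response and cancels phase distortion, keeping Ne/Pe peak
   latencies intact; this is standard offline ERP practice. It is applied
   to the continuous recording before epoching, so filter edge effects fall
   outside the trial windows. Pre-filtered distributions (the gaze-speller
   style profile) skip this stage.
2. **Epoching** over the half-open window `[onset, onset + duration)`,
   duration 1 s (or 0.5 s for the short-trial profile).
3. **Downsampling** to 64 samples per epoch (64 Hz for 1-s trials, 128 Hz
   for 0.5-s trials). Integer rate ratios use plain decimation — the 1–10 Hz
   bandpass already provides anti-alias protection for the 64 Hz target —
   and non-integer ratios fall back to polyphase resampling.
4. **Channel selection**: FCz and Cz, the frontocentral sites where ErrPs
   are strongest. Montages lacking FCz substitute Fz via an explicit,
   logged substitution table (configuration, not silent fallback).
5. **Amplitude scaling** ×1000, applied last. The order of scaling vs
   channel selection is mathematically immaterial; it is fixed as the final
   stage.

No artifact rejection, re-referencing or baseline correction is performed.

## Model

Two parallel feature extractors read the same (B, 1, 2, 64) batch.

* **Electrode branch (FE-E)**: Conv(1, 33) ×64 filters → BN → ReLU →
  AvgPool(1, 4) → Conv(1, 8) → BN → ReLU, collapsing each electrode's time
  course to a 64-dimensional embedding; the two electrode tokens then pass
  through a transformer encoder layer (d_model 64, 4 heads).
* **Temporal branch (FE-T)**: Conv(2, 33) ×64 filters collapses the
  electrode axis; AvgPool(1, 16) leaves 2 temporal tokens of 64 features,
  which pass through a second encoder layer.

Each branch adds the encoder input back onto the encoder output (an outer
residual on top of the encoder's internal ones) and layer-normalizes. The
two (2, 64) token maps are concatenated (electrode branch first — either
order gives width 256; one is fixed for reproducibility), flattened to 256
and classified through 256→64→2 fully connected layers with dropout after
each, ending in a softmax. Class 0 is "correct", class 1 is "error".

Design choices where the architecture description leaves freedom:

* Encoder layers are the post-norm transformer variant with feed-forward
  width 256 (4 × d_model) and ReLU, i.e. the original transformer defaults.
* No positional encoding: both token sequences have length 2 and carry
  conv-injected order information.
* ReLU after each conv + batch-norm pair (a conventional choice; only the
  BN placement is prescribed).
* Pooling is non-overlapping average pooling — forced by the shape chain
  (32/4 = 8, 32/16 = 2).
* Dropout rate 0.5 after both FC layers; inactive at inference.

The network and its training loop run on a small numpy reverse-mode
autodiff engine written for this package (`errpnet.nn`): broadcast
arithmetic, batched matmul, im2col convolution, fused normalization and
softmax primitives, SGD-with-momentum and Adam. Float64 throughout; every
primitive's gradient is verified against central finite differences in the
test suite. At this model size (~156k parameters, 2×64 inputs) a training
step on one CPU core takes tens of milliseconds, which the evaluation
protocols are sized around.

## Training strategy

* **Pretraining**: stratified 5-fold cross-validation. Within each fold the
  training partition is balanced with SVM-SMOTE and trained for 200 epochs
  (batch 32) with SGD (momentum 0.9), cosine learning-rate decay
  η(t) = lr_min + ½(η_max − lr_min)(1 + cos(πt/T)) from η_max = 1e-4 to 0
  (stepped per epoch), and label-smoothed cross-entropy (ε = 0.1, the
  technique's canonical value). The fold model with the highest validation
  accuracy (ties broken by lower final validation loss) becomes the
  transfer checkpoint.
* **Oversampling is per CV iteration**: the validation partition is carved
  out *before* SVM-SMOTE runs, so no synthetic sample can leak into
  validation. SVM-SMOTE fits an RBF-kernel SVM (C = 1) on the flattened
  128-dimensional epochs, unstandardized (inputs are already ×1000-scaled),
  and synthesizes minority samples from the minority support vectors:
  interpolation toward one of k = 5 minority neighbors when the support
  vector's m = 10-neighborhood is majority-dominated ("danger zone"),
  bounded extrapolation (step 0.5) away from the neighbor otherwise.
  Original rows are preserved verbatim and first; the majority class is
  untouched.
* **Fine-tuning**: all weights (no freezing) continue training on one
  target subject's data for 100 epochs with Adam at 1e-5 — ten times below
  the pretraining rate — under the same cosine decay, with no internal
  validation split. The fine-tuning set is also SVM-SMOTE-balanced (it is
  training data; its subject never appears in the test set). Adam uses its
  published defaults (β = 0.9/0.999, ε = 1e-8, no weight decay).

Training is reproducible: one seed determines fold splits, oversampling,
weight initialization, batch order and dropout masks.

## Evaluation protocols

Five scenarios, each a grid of (train unit, test unit) cells:

* **Leave-one-subject-out** (within one session): train on all other
  subjects with 5-fold CV under pretraining settings, test the best fold
  model on the held-out subject.
* **One-train-one-test**: 5-fold CV on a single subject under fine-tuning
  settings, test on every other subject. This is the non-pretrained
  baseline for transfer experiments.
* **Cross-task**: pretrain on the source task, fine-tune per target
  subject, test on each remaining target subject; reported together with
  the one-train-one-test baseline and per-column accuracy deltas.
* **Within-session**: per subject per session, 5-fold CV; the cell is the
  mean over held-out folds. The per-participant granularity (rather than
  pooled across participants) matches the per-participant reporting style
  of the protocol's tables; cross-subject pooling would mix
  non-exchangeable trials.
* **Cross-session**: per subject, train on one session (CV model
  selection), test on the other; both directions reported separately.

Metrics per cell, in percent: accuracy at a 0.5 threshold on the
error-class probability (no threshold is prescribed; 0.5 is the symmetric
choice), AUC (pairwise concordance with ties credited ½), error_rate
(error-class recall) and correct_rate (correct-class recall). Accuracy is
exactly the prevalence-weighted mean of the two recalls. Averages across
cells are unweighted. CSV output rounds to 2 decimals.

## Synthetic data

The generator emulates the statistical structure the method assumes, at
canonical shape directly (no continuous-EEG synthesis, no forward head
model):

* Error epochs: a biphasic template — negative Gaussian bump (Ne, default
  latency 0.25 s, width 0.05 s, amplitude −5 in scaled-microvolt units)
  followed by a positive one (Pe, 0.40 s, 0.07 s, +4) — on both channels
  with gains (1.0, 0.8), plus background noise. Correct epochs: background
  noise only. The published waveform description is qualitative, so these
  amplitudes/latencies are free parameters chosen to give a realistic
  single-trial SNR (|Ne| about twice the noise sd), not claims about real
  data.
* Background noise: 1/f-shaped by default (spectral shaping of white
  noise), sd 2.5.
* Error prevalence 0.205 — the prevalence observed in public ErrP corpora
  (≈1322 errors in 6437 trials); class counts are exact per subject.
* Per-subject variability: latency jitter sd 0.02 s, amplitude scale
  ~N(1, 0.1) truncated positive. Defaults: 6 subjects, 200 epochs/subject,
  2 sessions.
* Cross-task shift: a global amplitude scale, latency offset and noise
  multiplier applied to the target of a source/target pair generated from
  a deterministically split stream.
* A degraded-subject preset (template ×0.05, noise ×2) reproduces the
  low-signal-quality participant failure mode seen in real cohorts.

What passing tests on this data do **not** show: robustness to real EEG
artifacts (ocular, muscular), electrode drift, non-Gaussian noise, session
drift beyond fresh noise draws, or realistic cross-task differences beyond
the parametric shift model. Results on synthetic data validate the
machinery, not clinical performance.

## Numerical choices and degenerate inputs

* Normalization epsilons 1e-5 (batch/layer norm); batch-norm running-stat
  momentum 0.1; inference uses running statistics, so per-sample outputs
  are independent of batch composition.
* Non-finite training loss aborts with a diagnostic rather than continuing.
* AUC on single-class labels is reported as NaN with a warning.
* SVM-SMOTE with no minority support vectors (degenerate geometry) falls
  back to plain SMOTE over all minority rows, with a logged warning;
  zero-variance inputs degenerate to duplicating minority rows, which keeps
  the balance contract.
* Already-balanced input passes through oversampling unchanged.
* LDA baseline uses the svd solver, which stays defined for singular
  pooled covariance.

## Scaled-down test budgets

The test suite exercises the full protocols at reduced sizes chosen as the
smallest problems that still demonstrate each property: 2–4 subjects,
40–125 epochs per subject, 1–2 training epochs for structural checks, the
full 200-epoch budget for the separability check (one subject, 100 trials),
and 20 pretraining / 20 fine-tuning epochs over 10 seeds (~1,000 synthetic
epochs per seed) for the transfer-benefit property.

## Known limitations

* The MAT ingestion dialects document an assumed variable layout; the
  public archives' actual internal layouts must be confirmed before the
  ingestion path is trusted (the test suite never depends on it).
* Published accuracies on the three public EEG datasets are not reproduced
  here; they require external downloads and GPU-scale budgets. The package
  supports that path via the ingestion hook and full-size defaults.
* Binary classification only; inputs other than (2, 64) are a
  configuration-time error.
* No early stopping, no augmentation beyond SVM-SMOTE, no significance
  testing between methods.
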