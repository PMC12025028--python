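# Methods

`pouremg` implements an offline recognition pipeline for pouring-gesture
surface EMG: synthetic data generation, preprocessing, handcrafted
features, a from-scratch ConvMixer classifier with late feature fusion,
a three-level granular label taxonomy, and evaluation. This note records
the model assumptions, defaults and design choices in one place.

## The task and the label taxonomy

The study protocol records a seated subject pouring a bottle to the
**left**, **right** or **front** at wrist angles of **22.5°, 45°, 67.5°
or 90°**, plus a static **hold** (grip) gesture; each trial is 5 s of
gesture followed by 5 s of rest, recorded from four electrodes around
the thickest part of the forearm at 1925.9259 Hz.

Classes are organised as nested granules:

| level      | K  | classes                                         |
|------------|----|-------------------------------------------------|
| granular1  | 13 | every (direction, angle) pair + hold            |
| granular2  |  7 | {22.5°, 45°} vs {67.5°, 90°} per direction + hold |
| coarse     |  4 | left, right, front, hold                        |

A total coarsening function maps every finer class onto its primary
category, and `coarsen_probabilities` aggregates predicted class
probabilities by summing granule members *before* the argmax, so a
13-class model can always be scored as a 4-class model using its full
output distribution (an argmax-then-map mode also exists). Fine integer
ids follow the confusion-matrix numbering 1–4 left / 6–9 right / 11–14
front / 5 hold, with 10 accepted as an alias of 5 (the hold trial
occupies two slots per repetition block). The angle order *within* a
direction block (id 1 = left 22.5°, …, 4 = left 90°) is a frozen
convention; all internal logic works on (direction, angle), so the id
assignment is a single table.

## Synthetic signal model

The generator exists to make the pipeline testable with known ground
truth; it is *not* a physiological simulation. Per channel:

```
signal = A · envelope(t) · carrier(t) + powerline(t) + baseline(t)
```

* **carrier** — Gaussian white noise band-passed to 20–450 Hz (the
  typical sEMG energy band), normalised to unit RMS;
* **envelope** — zero at rest; during an active interval it equals the
  direction's per-channel gain profile times a monotone angle multiplier
  (linear, 0.4 at 22.5° → 1.0 at 90°), with 100 ms trapezoidal
  onset/offset ramps to avoid step discontinuities that would trivialise
  boundary windows;
* **powerline** — 50 Hz sinusoid, amplitude 10 % of the maximum active
  RMS (UK mains);
* **baseline** — broadband Gaussian noise, σ = 3 % of full scale.

Direction profiles give each pouring direction a distinct dominant
electrode (separability by construction); the shared angle multiplier
makes *adjacent angles of the same direction* the closest class pairs,
mirroring where a real classifier concentrates its errors. Hold has a
uniform low gain (0.15) rather than silence, because the protocol's hold
still grips the bottle.

What the generator does **not** emulate: motor-unit firing statistics,
electrode shift, inter-trial amplitude drift, fatigue, cross-talk
correlation structure, or movement artifacts. Passing the end-to-end
tests therefore shows the pipeline is correct and that the architecture
can exploit amplitude/spatial structure — it does not certify accuracy
on real recordings, whose difficulty this generator makes no claim to
match.

## Preprocessing

Offline chain, per channel, all filters zero-phase (forward–backward,
so features see no phase distortion):

1. IIR notch at 50 Hz, Q = 30;
2. Butterworth band-pass 20–450 Hz, order 4;
3. sliding windows of 250 ms advanced by 50 ms (80 % overlap — a dense
   decision stream), window length truncated to
   `floor(fs · 0.250) = 481` samples at the protocol rate.

Windows are cut only *inside* annotated intervals (half-open
`[start, end)` in seconds) and never straddle an interval boundary, so
every window carries exactly one unambiguous label; an interval shorter
than one window yields none (warning, not an error). All of the above
(frequencies, Q, order, window/step) are configuration-exposed.

## Handcrafted features

Per channel per window, concatenated channel-major into 16 dimensions:

* RMS = sqrt(1/N Σ xᵢ²)
* VAR = Σ xᵢ² / (N−1) — deliberately the mean-power form without mean
  subtraction (akin to simple square integral / mean power), not the
  statistical variance; the conventional EMG feature name is kept.
* ZC  = #{i : −xᵢ·xᵢ₊₁ > ε}, with sgn(x) = 1 iff x > ε; the deadband
  default ε = 0.01 mV suppresses noise-floor crossings (analytic tests
  use ε = 0).
* WL  = Σ |xᵢ₊₁ − xᵢ|

Features are computed on *filtered* windows (a flag to skip filtering
exists at pipeline level by overriding the filter band). Before fusion
or classical classifiers they are z-scored with statistics fitted on
the training split only; near-constant dimensions have their scale
clamped to 1e-8 to avoid blow-ups.

## ConvMixer

Implemented directly on numpy arrays — forward pass, analytic
backpropagation and an Adam optimizer — so that training is bit-for-bit
reproducible from a seed on any platform. A finite-difference gradient
check of the full network is part of the development validation; the
test suite checks each block against naive convolution oracles.

Architecture on a 4 × N window (single-plane image):

1. **Patch embedding**: Conv2D with kernel = stride = (4, p) — spans all
   four electrode rows and p time samples — giving floor(N/p) patches
   embedded in h dimensions; then GELU + batch norm. Defaults p = 13,
   h = 64 → 37 patches at N = 481.
2. **d mixer blocks** (default d = 4): depthwise conv (groups = h, same
   padding, kernel 9) → GELU → BN, wrapped in a residual connection
   (`x + BN(GELU(DWConv(x)))`, as in the original ConvMixer; a flag
   disables the residual); then pointwise 1×1 conv → GELU → BN.
3. **Head**: global average pool over patches; with
   `fusion_mode="late_concat"` the pooled h-vector is concatenated with
   the standardized 16-dim feature vector before the linear classifier.

Late fusion was chosen over injecting features into the patch embedding
because it keeps the embedding's input shape well-defined and lets the
classifier weight learned and handcrafted evidence independently; the
`FeatureDenseNet` (16 → h → K dense head) is the features-only
counterpart used in comparisons.

Batch norm uses batch statistics during training, running estimates
(momentum 0.1) at inference, ε = 1e-5. GELU is the exact erf form.
Training: softmax cross-entropy, Adam at 1e-3, batch 32; weight init,
feature-scaler fit and epoch shuffles all derive from the config seed.

## Evaluation

Confusion matrices have true classes on rows. Accuracy is
trace/total; sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are
computed one-vs-rest per class and macro-averaged (unweighted mean);
classes with a zero denominator (absent from the test split, or with no
negatives) are excluded from the macro mean rather than scored 0, so
small splits are not penalised for empty classes. Coarsened confusion
matrices are `G · C · Gᵀ` for the 0/1 granule-membership matrix G, which
preserves the total count. Classical baselines (SVM, random forest,
LDA) run on the 16 standardized features with library defaults and a
fixed seed, on the same splits as the deep model.

## Splits, sizes, runtimes

Default split: stratified by window, 60/20/20 train/val/test, seeded.
Note that 80 %-overlapping windows from the same trial are highly
correlated, so by-window splitting is optimistic; on synthetic data this
is immaterial (every window's ground truth is exact), but for real
recordings a per-trial (group) split is the right protocol.

The default study is 3 repetitions × (12 pouring gestures + 2 hold
slots) = 42 trials → 4032 windows of 4 × 481 samples. At this size one
training epoch of the default model takes seconds on a single CPU and
the task converges within a handful of epochs, so the pipeline default
is 10 epochs (the standalone `ModelConfig` default is 50); a full
generate→train→evaluate run completes in minutes on one CPU.

## Numerical and degenerate-input choices

* Window length and step truncate fractional samples (floor).
* Annotation intervals are validated as non-overlapping and inside the
  recording; violations are format errors naming file and line.
* Probability vectors entering coarsening must sum to 1 within 1e-6.
* The hold granule is a singleton at every level and always the last
  class index; coarse order is (left, right, front, hold).
* Coarsening from a coarser to a finer level is rejected (not
  invertible).
* Zero training classes, absent classes, feature-dimension mismatches
  and sub-Nyquist violations all raise `ValueError` before any work.

## Known limitations

* The synthetic generator's simplicity means reported accuracies
  characterise the pipeline, not real-world difficulty; headline
  numbers from restricted clinical data cannot be reproduced here.
* Single-subject design: no cross-subject normalisation or transfer.
* The numpy network is CPU-only and desk-scale by design; it is not a
  general deep-learning framework.
* Only the four time-domain features are implemented; frequency-domain
  and autoregressive features are out of scope.
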