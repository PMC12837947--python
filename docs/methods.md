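# Methods

## Signal model and feature extraction

Clips are mono waveforms at f₀ = 8 kHz, amplitude-normalised to [−1, 1] and
forced to exactly N = f₀·T = 8000 samples (T = 1 s): shorter events are
zero-padded symmetrically, longer recordings cropped (centre crop by
default; a seeded random crop is available for augmentation-style use).

The STFT uses a 256-sample periodic Hann window with a 128-sample hop.
**Framing convention.** The naive arithmetic 1 + (8000 − 256)/128 gives the
non-integer 61.5; this package keeps the final partial frame by zero-padding
the signal tail, giving `Tframe = 1 + ceil((N − n_fft)/hop) = 62` frames.
All downstream shapes (64×62 features, 62×62 temporal Gram matrices) follow
from this choice.

The power spectrum (squared magnitude) is projected through a 64-filter
triangular HTK-mel bank spanning 0–4000 Hz. The upper edge is the Nyquist
frequency; cough energy nominally extends to ~5 kHz, but at an 8 kHz sample
rate nothing above 4 kHz exists to be represented. Band energies are floored
at `floor_eps = 1e-10` before the logarithm, so silence maps to the finite
constant ln(1e-10) rather than −∞. The **natural logarithm** is the default;
base-10 is available via `log_base="10"` (the two differ only by a constant
factor, which batch-norm downstream absorbs anyway).

One-hot labels are ordered `[cough, noise]`: component 1 of the label
vector, and column 0 of every probability array, is the cough class.

## Frozen backbone

The backbone is the canonical CNN14 convolutional trunk: an input batch-norm
over the 64 mel bins, six VGG-style blocks of two 3×3 conv + batch-norm +
ReLU layers with channel widths 64, 128, 256, 512, 1024, 2048, 2×2 average
pooling after the first five blocks, and global average pooling of the final
2048-channel map into the clip embedding g₁₄. A description of this network
as "14 generically cascaded conv layers" is treated as schematic: the
canonical block topology is what published AudioSet-pretrained checkpoints
fit, and checkpoint compatibility is the only defensible reconstruction.

The backbone is frozen in the strict sense: batch-norm always runs with its
stored statistics, no tensor ever enters the optimiser, and gradient flow
arriving at the fusion point is discarded rather than propagated (tests
assert bit-identity of every backbone tensor across training). Because the
backbone is a constant function of its input, clip embeddings are computed
once and cached; training then touches only the lightweight branches.

**Weight sources.** Default: a reproducible He-initialised random backbone.
Random conv stacks expect roughly centred inputs, while Log-Mel features
live around −23…+2 nats, so the input batch-norm statistics are fitted once
on the training-set features at model assembly and then frozen — this is
part of the (frozen) backbone definition, not a trainable component.
Alternatively `load_pretrained` reads an HDF5 archive of the published
CNN14 tensors under the documented name mapping
(`pigcough.backbone.PRETRAINED_NAME_MAP`); the archive is validated
tensor-by-tensor and every missing or mis-shaped entry is reported by name.

## TFDS descriptor

The trainable branch summarises second-order time–frequency structure:

1. 1×1 convolution over the mel axis to S = 32 sub-bands, batch-norm
   (batch statistics during training, running statistics at inference,
   momentum 0.1), ReLU → Z ∈ ℝ^{32×62}.
2. Temporal Gram matrix C_t = ZᵀZ (frame-by-frame inner products, 62×62)
   and spectral Gram matrix C_f = ZZᵀ (band-by-band, 32×32). These are
   **raw uncentred, unnormalised** products — no mean subtraction, no
   division by the frame count. The matrix-product orientations are fixed by
   the declared semantics (temporal = frame×frame, spectral = band×band);
   a formulation writing the transposes the other way around is reconciled
   in favour of the named shapes.
3. Adaptive average pooling to T_max = 25 and S_max = 16, with region
   boundaries `[floor(i·n/m), ceil((i+1)·n/m))` — the standard
   deep-learning adaptive-pool contract. Pooling is implemented as a
   pre-computed averaging matrix P, `C' = P C Pᵀ`, which also makes the
   backward pass (`Pᵀ dC' P`) exact.
4. Row-major flatten of pooled C_t then pooled C_f (25² + 16² = 881 dims),
   and a ReLU linear projection to H = 128.

All gradients of this chain — including through training-mode batch-norm
statistics and through the bilinear Gram maps (dZ = Z(dC_t + dC_tᵀ) +
(dC_f + dC_fᵀ)Z) — are implemented in closed form and verified against
central finite differences to ≤ 1e-6.

## Fusion head and ablation variants

The fused feature is the **concatenation** g = [g₁₄; g_tfds] ∈ ℝ^{2176}
(2048 + 128; an additive reading of the fusion is untenable at these
dimensions and is covered instead by the explicit add-fusion variant).
Inverted dropout with p = 0.2 multiplies by a Bernoulli keep-mask and
rescales by 1/(1−p) during training, and is the identity at inference, so
E[h] = g. One mask is drawn per item per forward pass from the run's
generator. The head is a single affine map to two logits followed by a
max-subtracted (overflow-safe) softmax.

Ablation variants are configuration switches: *no TFDS* (head on g₁₄ only),
*no backbone* (head on g_tfds only), *add fusion* (g₁₄ linearly projected to
128 dims, initialised like the head and trained at the head's learning rate,
summed with g_tfds), and *no stratified learning rate* (uniform 3×10⁻⁴, the
TFDS-branch rate, for all groups).

## Training mathematics

Loss: mean cross-entropy L = −(1/K) Σᵢ (y_{i,cough} ln p_{i,cough} +
y_{i,noise} ln p_{i,noise}), with the true-class probability floored at
1e-12 (with a warning) to keep early saturated batches finite.

The softmax-layer gradient is ∂L/∂zᵢ = (pᵢ − yᵢ)/K; head gradients follow as
∂L/∂W = (∂L/∂z)ᵀ h and ∂L/∂b = Σᵢ ∂L/∂zᵢ, concatenated into the flat vector
[vec(∂L/∂W); ∂L/∂b] (4354 entries for the default head).

Per optimisation step, on the flattened gradient:

* weight decay g_reg = g + λθ with λ = 10⁻⁵, added to the gradient (not
  decoupled). Decay and clipping are applied to **all** trainable groups —
  they are presented as global training regularisation — with a
  `decay_scope="head"` switch for literal head-only replication;
* global-norm clipping over the concatenation of all trainable group
  gradients: g_clip = g_reg if ‖g_reg‖₂ ≤ τ else τ·g_reg/‖g_reg‖₂, τ = 0.3;
* bias-corrected Adam with β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ (standard values;
  the hyperparameters are named but not pinned in the source description).

Learning rates are stratified: 3×10⁻⁴ for the TFDS group, 10⁻³ for the head
(and the add-fusion projection, which behaves as part of the head). Batch
size 8; the last incomplete batch is used as-is. Validation runs every 5
epochs; the best-validation parameters (including the TFDS batch-norm
running statistics) are restored at the end, and training stops early after
3 validation checks without improvement — periodic validation is the stated
overfitting control, and this patience rule makes it operational.

The 10-step optimiser trace, decay and clipping included, is verified
against an independent scalar re-implementation to ≤ 1e-10 per parameter.

## Evaluation protocol

* Accuracy, precision, recall, F1 = 2TP/(2TP + FP + FN) with cough as the
  positive class; undefined 0/0 ratios are reported as 0 with a warning.
* Stratified 85:15 hold-out: the test count is the nearest integer to
  0.15·n, allocated per class by largest remainder (697 clips → 105 test).
* Stratified 5-fold CV on the train–validation set; per-metric mean, sd
  (ddof = 1) and the two-sided 95% t interval x̄ ± t₀.₉₇₅,₄ · s/√k. The
  standard-error form s/√k is used (a printed variant omitting the square
  root is a typographical slip inconsistent with t-interval usage).
* Permutation test with N = 100 label shuffles and
  p = (#{S_perm ≥ S_true} + 1)/(N + 1). The smallest attainable p is
  1/(N+1) ≈ 0.0099; claims of p < 0.001 under this formula with N = 100 are
  unreachable, and the implementation reports the floor honestly. Default
  rescoring keeps the predictions fixed (cheap and deterministic); a
  retrain-per-permutation mode can be composed from the API but is not the
  default.
* Calibration: M = 10 equal-width bins on the cough probability; a value on
  a bin's right edge joins the lower bin except 1.0, which joins the top
  bin. acc(B_m) is the empirical cough fraction, conf(B_m) the mean
  predicted probability; ECE is the count-weighted mean absolute gap.
* AUPRC by step-wise average precision (Σ ΔR·P, no trapezoidal
  interpolation), the conservative convention for imbalanced data.

## Synthetic corpus

The generator emulates the documented signatures rather than the recordings
themselves (which are not deposited): coughs are 1–3 sharp-attack
(5 ms rise) exponentially decaying bursts of 1–3 kHz band-passed noise,
total event duration drawn from 0.2–0.5 s (the acquisition-level figure is
used where the source's three quoted ranges disagree), peak amplitude
0.4 ± 15%, centred in a 1 s clip; noise clips are stationary 0.1–2 kHz
coloured noise (an intermittent-hum mode adds a slow AM mains-like
component), RMS 0.05 — no farm signal-to-noise statistics are documented, so
the RMS is exposed as a parameter rather than guessed. The default corpus is
107 cough / 590 noise clips, matching the study-scale class imbalance.
Per-clip seeds spawn from one master seed; corpora are byte-reproducible.

The classes are separable by a single threshold on the 1–3 kHz vs
0.1–2 kHz band-energy ratio (≥ 95% accuracy by construction, asserted in
tests). This guarantees the learning task is solvable, so end-to-end
training assertions are meaningful — but it also means passing them shows
implementation correctness, **not** field performance: real barn audio has
overlapping spectra, reverberation, and non-cough vocalisations the
generator deliberately omits. Metrics reported on this corpus (typically
perfect separation) are upper bounds with no claim about real farms.

## Problem sizes and reproducibility

Default experiment scale: 697 one-second clips, 50 training epochs (early
stopping usually ends much sooner on the separable corpus), 100
permutations, 5 CV folds. The frozen backbone embeds the corpus once
(~1 minute in float32 via im2col GEMM convolutions); training the 119,394
trainable scalars takes seconds per run. A single run seed fans out to
per-stage seeds via CRC-32-keyed `SeedSequence`s, so stages are individually
reproducible and mutually decoupled.

## Known limitations

* The published pretrained CNN14 checkpoint is a PyTorch archive; this
  package consumes an HDF5 conversion of it (mapping documented in
  `PRETRAINED_NAME_MAP`) and defaults to a random frozen backbone, so
  absolute performance with AudioSet features is not evaluated here.
* The trainable-parameter count is emitted as computed (119,394 under
  defaults: 115,040 TFDS + 4354 head). A folklore figure of "about 89,000"
  is not reproducible from the stated dimensions — the 881→128 projection
  alone holds 112,768 weights.
* The permutation test's default fixed-prediction rescoring tests the
  association between predictions and labels, not the full training
  pipeline's null distribution.
* Binary task only (cough vs noise); no cough subtyping, no multi-label
  soundscape handling, no streaming inference.
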