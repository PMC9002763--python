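# Methods

This note documents the model, the numerical and design choices behind
`neuroseg3d`, what the synthetic phantoms do and do not establish, and the
known limitations.

## Architecture

The network maps an intensity block (H, W, D, 1) to per-voxel class
probabilities (H, W, D, S+1).

**Encoder.** A stack of stride-1, same-padded 3×3×3 convolutions with ReLU
(default widths 16, 16). There is deliberately no pooling and no striding:
the encoder extracts local features at full spatial resolution and the
global context is left to the attention bottleneck. The encoder depth and
widths are open design parameters; the defaults keep the token flatten
(P³·C′ → d_model) tractable, and both are configurable
(`ModelConfig.encoder_channels`).

**Tokenization.** The feature maps are partitioned into nonoverlapping
P×P×P blocks (patch resolution P, default 8, power of two). Each block is
flattened and linearly projected to d_model = 64, and a learned positional
embedding E_pos ∈ ℝ^{N×d_model} (initial sd 0.02) restores spatial order;
N = (H/P)(W/P)(D/P). For the default 64³ input, P=8 gives 512 tokens and
P=16 gives 64.

**Transformer bottleneck.** I = 4 pre-norm layers:
x ← x + MHSA(LN(x)); x ← x + MLP(LN(x)). MHSA uses h = 4 heads of width
d_k = d_v = d_model/h = 16; attention is softmax(Q Kᵀ/√d_k) V per head,
heads concatenated and projected by W^O. Projections carry no biases
(matching the formulation the architecture follows). The MLP has one ReLU
hidden layer of width 192 followed by dropout (rate 0.1, training only).
The layer-norm epsilon is 1e-4; the source description's "normalization
rate 0.0001" is interpreted as this epsilon, it being the only
normalization hyperparameter in the stack.

**Decoder.** Tokens are reshaped to the (H/P, W/P, D/P, d_model) grid, then
log₂P stages of nearest-neighbour ×2 upsampling + 3×3×3 conv + ReLU
(default widths halve from d_model, floored at 16). At full resolution the
encoder features arrive through a **Res path** — a chain of residual units,
each ReLU(conv3×3×3(x) + conv1×1×1(x)), one unit by default — and are
fused by channel concatenation + conv (the U-Net convention; the source
does not state sum vs concat). A 1×1×1 conv head produces S+1 logits;
softmax gives probabilities.

**Initialization.** Convolutions use He initialization; the patch embedding
uses sd √(1/fan_in). Two places are zero-initialised as a deliberate
design choice: the residual output projections of every transformer layer
(W^O and the second MLP matrix), so each layer starts as the identity, and
the classification head, so the initial prediction is exactly uniform.
This identity-residual start — standard practice for transformer residual
branches — changes desk-scale trainability dramatically: on the 32³
three-structure overfit task the macro Dice after 200 optimizer steps is
≈ 0.975 versus ≈ 0.55 with plain Gaussian init. Gradients still reach the
zero blocks (their own gradients are nonzero from the first step).

**Token-count formula.** The source text prints a token count
N = H·W·D·C/16 that is inconsistent with its own 8×8×8 patch resolution;
the geometric partition N = (H/P)(W/P)(D/P) is implemented instead, with
the embedding width L housed as d_model.

## Objective

`combined_loss = λ·L_Dice + (1−λ)·L_focal`, λ = 0.5 by default (the mixing
rule is not stated at the source; an equal convex mix is exposed as
`lambda_mix`).

* **Weighted Dice** is one *global* ratio, not a per-class mean:
  L_D = 1 − 2·Σ_j w_j Σ_i y_ij p_ij / Σ_j w_j Σ_i (y_ij + p_ij). It is 0
  exactly at a perfect prediction and invariant to rescaling all w_j.
* **Focal loss** is the voxel mean of −α_t (1−p_t)^γ log p_t with γ = 2
  (the canonical focusing value; unstated at the source) and p_t clipped to
  [1e-7, 1] to keep the log finite.
* **Median frequency balancing**: freq(c) = voxels of class c / total
  voxels of the volumes where c appears; α_c = median(freq)/freq(c). The
  background participates in both losses and in the weights by default
  (flags to exclude); the focal α_t is tied to the same weights, which is
  the natural reading of "class weights used in the loss functions".

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with base LR 1e-3 and batch size 8.
The LR is flat for the first 12 epochs, then decays as
base·(epoch − 11)^(−0.5) — "decreased after the 12th iteration to a power
of 0.5" read as an exponent with epoch-indexed iterations; both the unit
and the form are ambiguous at the source and the epoch at which the decay
starts is configurable. Class weights are computed from the training split
only. Early stopping monitors validation macro Dice (patience 10 by
default); the best-validation parameters are restored and checkpointed.
The backend is pure numpy (float32), so runs are bit-deterministic for a
fixed seed regardless of the `deterministic_mode` flag.

## Synthetic phantoms

The generator emulates the *statistics* of a brain parcellation task, not
its anatomy: S ellipsoidal structures (random centers, anisotropic
semi-axes, random rotations) carved into a background cube, with target
volumes decaying as rank^(−q), q = 1.5 by default — a qualitative match to
the heavy-tailed structure-size distribution of real parcellations, whose
exact counts are not published numerically. Foreground occupies 30% of the
volume by default. Structures are placed largest-first; candidate
placements overlapping existing structures by more than 5% of their own
volume are retried (bounded), so realised volumes track the rank targets
and pooled class counts are monotone in rank. Each class has a distinct
mean intensity (background 0.05, structures evenly spaced on [0.25,
0.95]) plus Gaussian noise of sd 0.05 — separations of several σ, i.e. an
easy contrast compared with real T1 tissue distributions.

Consequently a green overfit test establishes that the architecture,
autodiff, losses and optimizer can jointly represent and learn a 3D
multi-structure segmentation — and nothing about accuracy on real MRI,
where boundaries are not intensity-separable and generalisation (not fit)
is the question. The phantom deliberately omits MRI physics: no bias
field, no partial-volume effects, no cortical geometry.

### Patch-resolution contrast

A documented negative result: on these phantoms the finer P=8 tokenization
does *not* beat P=16 at an equal step budget (P=16 ends ≈ 0.005–0.01 macro
Dice ahead, consistently across phantom seeds). With intensity-separable
structures and a full-resolution Res-path skip, accuracy is not limited by
bottleneck token resolution; the P=16 model simply has ~8× more embedding
parameters and one extra decoder stage and therefore fits a single volume
slightly faster. The reported advantage of P=8 concerns boundary detail on
real cortical geometry, which this phantom world cannot exhibit. The
corresponding acceptance test is kept as specified and fails honestly.

## Numerical conventions

* Histogram equalization uses a 256-bin bin-CDF lookup on the volume's own
  range (each voxel maps to the cumulative frequency of its bin), followed
  by min-max scaling to [0, 1]. This is the classic non-interpolated
  convention; scikit-image's `equalize_hist` interpolates between bin
  centers and differs at coarse bin counts. Constant volumes normalise to
  zero with a warning.
* Empty-slice removal crops only leading/trailing slices whose intensities
  are all ≤ a threshold (default exactly 0), never interior slices.
* Patching zero-pads to the next multiple of the patch size (padding is
  background, semantically air); stacks are ordered lexicographically by
  block index and reassembly is bit-exact.
* Metric conventions: a class empty in both volumes scores 1.0 and is
  flagged; precision with no predicted positives is 1 if the class has no
  true voxels, else 0 (recall symmetric). The macro average excludes
  background; the support-weighted average includes it by default — the
  convention under which a weighted Dice can exceed every structure's
  individual Dice.
* The 8:2 split is stratified by sub-dataset of origin; every stratum with
  ≥ 2 members contributes at least one validation volume; singletons go to
  training with a warning.
* Probability sums after softmax are exact to float32 roundoff (≈ 1e-7);
  the forward pass checks finiteness after the encoder, transformer and
  decoder stages and raises naming the stage.

## Limitations

* No GPU path and no framework interop; the numpy backend is desk-scale
  (seconds per 64³ patch forward+backward, minutes for small overfit
  runs), not suitable for training on a real 101-volume dataset.
* Nearest-neighbour upsampling only; transposed convolutions are not
  implemented.
* No data augmentation (none is described at the source).
* DICOM and FreeSurfer `.mgz` inputs are out of scope (convert to NIfTI
  first); volumes are processed in stored axis order without
  reorientation.
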