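# Methods

## Problem and representation

`glioseg` segments brain tumors in co-registered multi-modal 3D volumes
(four MRI-like channels) into the BraTS label vocabulary {0 background,
1 NCR, 2 ED, 4 ET}. Because challenge scoring is region-based, the
networks do not predict these mutually exclusive classes; they predict the
three *overlapping* regions

- WT (whole tumor) = {1, 2, 4},
- TC (tumor core) = {1, 4},
- ET (enhancing tumor) = {4},

one independent sigmoid channel each, in that fixed order. The nesting
ET ⊆ TC ⊆ WT holds for every mask derived from labels, and the decoding
cascade (below) re-imposes it on predictions. An optional fifth input
channel marks *salient* voxels — voxels that are nonzero in any modality —
which on skull-stripped data is a brain mask; it gives the network an
explicit in-brain/out-of-brain cue that is otherwise entangled with
intensity.

## Networks

All four variants are U-shaped 3D encoder-decoders built from one block:
3³ convolution (stride 1 or 2) → instance normalization → LeakyReLU with
negative slope 0.01. Encoder stage ℓ > 0 opens with a stride-2 block, so a
depth-7 encoder takes a 128³ patch to a 2³ bottleneck. Channels follow
`min(base · 2^ℓ, cap)`; the defaults (base 64, cap 512, depth 7) give the
schedule 64→512, and base 32/cap 320 at depth 6 reproduces the smaller
32→320 baseline. The decoder mirrors the encoder: kernel-2/stride-2
transposed convolution, concatenation with the same-level skip, one
stride-1 block.

- `unet` — the plain network above.
- `res_unet` — every block gains an identity shortcut; a 1³ (strided)
  projection reconciles channel/stride mismatches.
- `attention_unet` — before concatenation each skip is reweighted by an
  additive attention gate α = σ(ψ(act(Wx·skip + Wg·up(gate)))) with the
  gating signal from the coarser decoder level; α ∈ [0, 1] has one channel
  and is broadcast over the skip's channels. The intermediate width is
  half the skip channels.
- `ae_unet` — residual blocks plus a variational-autoencoder branch off
  the bottleneck: two 1³ convolutions pooled globally give μ and log σ²
  of a 256-dimensional latent (configurable); z = μ + σ·ε is decoded by a
  slim mirror of the encoder back to the input's channels and extent.
  The branch exists purely to regularize the shared encoder during
  training and is ignored at inference.

Output heads are 1³ convolutions + sigmoid. With deep supervision
(default), heads sit on the last three decoder levels — full, 1/2 and 1/4
resolution (A = 1..3, clamped to depth − 1 heads for very shallow nets).
Inputs whose extent is not divisible by 2^(depth−1) are zero-padded
symmetrically and every head is cropped back to ceil(extent / 2^(A−1)).

### The numerical engine

No deep-learning framework is part of the dependency set; the package
ships a small reverse-mode autodiff engine over numpy (`glioseg.nn`):
a `Tensor` records a graph of vector-Jacobian closures, convolution is
im2col in channels-last layout (the patch-unfold copy then reads memory
almost sequentially), the input gradient is computed as a correlation of
the dilated output gradient with the flipped kernel (another im2col
matmul rather than a scatter), and the kernel-2/stride-2 transposed
convolution reduces to a tensordot because its output blocks do not
overlap. Adam, ReduceLROnPlateau and early stopping are implemented
directly. Every primitive's gradient is tested against central finite
differences. Parameters and activations are float32.

## Losses

The training objective is the convex combination

L = α · Dice + (1 − α) · secondary,  α = 0.7 by default,

where Dice is the soft *batch* form — intersection and mask sums pooled
over all items of the batch before the ratio, one ratio per region
channel, stabilized by a smooth term (1e-5) — and the secondary term is
voxel-wise binary cross-entropy or focal loss (−(1−p_t)^γ log p_t,
γ = 2), selected by configuration; probabilities are clamped to
[1e-7, 1 − 1e-7] inside the logarithms. At γ = 0 focal reduces exactly to
BCE. With deep supervision the combined loss is evaluated per head
against targets downsampled by nearest neighbor (anchored at index 0,
source index i·f, so nesting is preserved voxel-wise) and aggregated as
Σ w_A L_A / Σ w_A with equal default weights; the normalized form keeps
the loss scale comparable with and without supervision. For `ae_unet`
the objective adds mean-squared reconstruction error and the closed-form
KL divergence to a standard normal, each weighted 0.1 by default (the
weights are not prescribed anywhere; 0.1 keeps the branch subordinate to
the segmentation terms).

## Training

Adam with learning rate 1e-4 and weight decay 1e-5, batch size 2, patch
size 128³ (every axis must be ≥ 2^(depth−1)); ReduceLROnPlateau on the
validation loss (factor 0.5, patience 5, floor 1e-6 — values chosen here,
not prescribed); early stopping with patience 10. Patches are sampled
with foreground bias: with probability `fg_bias` (default 0.5) the patch
center is a uniformly drawn tumor voxel, clipped so the window stays in
bounds. The bias is an explicit extension knob: the sampling policy is
otherwise unconstrained, and uniform sampling on sparse tumors starves
the region losses. Each epoch visits every training case
`patches_per_case` times (default 2). Validation uses one deterministic
patch per held-out case, centered on the tumor centroid. The per-epoch
history records each head's loss (columns L1, L2, L3), the total, the
validation loss and the learning rate; the best-validation parameters are
returned in a checkpoint that embeds the full configuration so `predict`
can rebuild the network. Case splits come from a 20% holdout or from
deterministic k-fold splits (default k = 5; validation fold sizes differ
by at most one).

## Inference and post-processing

Whole volumes of any extent are tiled by patch-sized windows whose
origins advance by half a patch per axis, the last window clamped to the
boundary; axes shorter than the patch are zero-padded symmetrically.
Window predictions are blended with a center-peaked Gaussian importance
map (σ = patch/8 per axis, floored at 1e-3 so weights stay positive) and
normalized by the accumulated weights — exact for constant fields, which
the tests exploit. Test-time augmentation runs the tiled prediction on
all 8 axis-flip variants, un-flips, and averages the probabilities
(post-sigmoid).

Probabilities become labels by a strict-threshold cascade: WT < 0.45 →
background; else TC < 0.40 → ED; else ET < 0.45 → NCR; else ET. Two
enhancing-tumor clean-up stages follow (both configurable, both only ever
remove ET): connected components (26-connectivity by default) smaller
than 16 voxels with mean ET probability below 0.9 become NCR; then, if
fewer than 73 ET voxels remain in total and their mean probability is
below 0.9, all ET becomes NCR. The two stages are kept separate because
they act at different granularities; running the per-component rule first
preserves each as stated. The 0.9 clauses use the mean probability over
the affected voxels.

## Metrics

Per-region Dice 2|A∩B|/(|A|+|B|) with the empty-mask convention: both
masks empty scores 1, exactly one empty scores 0. The convention is
usually motivated by ET (where small false positives are
punishing); it is applied uniformly to all three regions so the metric is
total, and reports keep regions separate so the choice stays visible.
Reports aggregate per case, per fold and overall.

## Synthetic phantoms

The generator emulates the *structure* of skull-stripped multi-modal
glioma data, not MRI physics: a brain ellipsoid of nonzero intensity on
an exactly-zero background, three concentric tumor ellipsoids (ET inside
TC inside WT) with jittered radii (defaults 14/9/5 voxels in a 64³
volume) and center (±3 voxels), per-tissue mean intensities in each of
four channels (edema brightest in the T2/FLAIR-like channels, enhancing
tumor in the T1ce-like channel, i.i.d. Gaussian noise with σ = 0.05
inside the brain). Everything is a pure function of (seed, case index),
so datasets regenerate bit-identically from their manifest. At zero
noise an intensity threshold alone segments WT with Dice > 0.95 — the
learnability floor the test suite checks. What phantoms do not exhibit:
bias fields, partial-volume effects, anatomical context, irregular tumor
shapes, inter-scanner variation. Passing tests on phantoms therefore
demonstrates that the pipeline's machinery is correct and that the
networks can fit separable structure — not clinical performance.

## Scaled-down training checks

The test suite trains the `res_unet` variant with deep supervision at
desk scale — depth 4, base 8 channels, 32³ patches, batch 2, Adam 1e-4,
α = 0.7 Dice + focal, 16 phantom training cases, 30 epochs of 16 steps —
and segments 4 held-out phantoms with the full sliding-window + flip-TTA
+ post-processing pipeline, using the salient-voxel input channel (the
best-performing full-scale configuration). A companion check
trains matched deep-supervision/no-supervision pairs for a few epochs
across seeds and compares each run's own final training objective — the
quantity loss-convergence figures plot. (Comparing the final-head loss
alone would be biased toward the no-supervision run at short horizons,
where the single head receives all of the gradient.) These sizes are the package's chosen
desk-scale study conditions; the full-scale configuration (128³ patches,
depth 7, 64→512 channels) is exercised for shape and gradient contracts
only.

## Known limitations

- CPU-only: minutes per desk-scale training run; the full-scale
  configuration is impractical to train here.
- Instance normalization computes per-patch statistics, so inference on
  background-only windows sees a different statistic distribution than
  foreground-biased training patches; the salient channel mitigates this.
- No training-time augmentation (none is prescribed); TTA only.
- The hyperparameter sweep utility (`training.grid_search`) does
  exhaustive grid evaluation only and claims no fidelity to any
  particular search protocol.
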