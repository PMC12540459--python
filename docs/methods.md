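# Methods

This note documents the models, numerical conventions and design choices in
`lemunet`, and what the synthetic experiments do and do not establish.

## Problem setting

Focal cortical dysplasia lesions are small, low-contrast and have blurred
edges; the segmentation target is a binary lesion mask on co-registered
multimodal volumes (T1 required, FLAIR and PET optional, T1 always channel
0).  All volumes are assumed co-registered to a common grid; registration,
skull stripping and bias-field correction are out of scope.

## Backbone

A MedNeXt-style encoder-decoder built from inverted-bottleneck residual
blocks:

* depthwise k³ convolution (one filter per channel, zero padding k//2),
* group normalisation with one group per channel (affine),
* 1×1×1 expansion to R·C channels, GELU, 1×1×1 compression back to C,
* identity residual.

Down blocks use a stride-2 depthwise convolution with a stride-2 1×1×1
residual projection and double the width; up blocks use the transposed
variants and halve it.  Stage widths are C, 2C, 4C, 8C with a 16C
bottleneck; skips are additive.  Deep supervision: a 1×1×1 softmax head at
each of the five decoder resolutions (full resolution first).

Size configurations (both C = 32, kernel 3):

| size | block counts B | expansion ratios R |
|------|----------------|--------------------|
| M    | 3,4,4,4,4,4,4,4,3 | 2,3,4,4,4,4,4,3,2 |
| L    | 3,4,8,8,8,8,8,4,3 | 3,4,8,8,8,8,8,4,3 |

plus a `tiny` configuration (configurable C, one block per stage, R = 2) for
CPU-scale experiments.

Normalisation inside blocks is per-channel group norm rather than batch
norm because the training batch size is 2; batch norm is kept where the
edge-attention equations specify BN.  With batch statistics computed from a
one- or two-sample batch we use the current-batch statistics in both
training and inference (no running averages); this keeps the model a pure
function of (parameters, input) and makes repeated forward passes
bit-identical.  The cost is a train/infer consistency approximation that
standard running-stat BN would not make.

**Parameter totals.**  With three input channels and two classes the
backbone counts 17,550,954 (M) and 61,781,258 (L) trainable scalars; the
full edge-guided model counts 17,702,132.  Every convolution carries a bias
and every norm an affine pair; biases that are algebraically cancelled by a
following normalisation (e.g. the depthwise conv bias) are still counted —
they receive zero gradient but remain trainable parameters, matching the
reference convention.

## Laplacian pyramid

Classic Burt–Adelson conventions, chosen for their exactness properties:

* `gs`: separable 5-tap binomial [1,4,6,4,1]/16 — unit sum and symmetric,
  so constants are reproduced exactly and interior affine ramps preserved;
* borders: mirror reflection (no edge duplication), preserving constants at
  the boundary, so a spatially constant volume yields identically zero
  Laplacian levels;
* `d`: decimation keeping voxels (0, 2, 4, ...) — ceil(n/2) per axis;
* `up`: separable linear interpolation with endpoint alignment
  (src = i·(n−1)/(m−1)) to an explicit target shape in {2n−1, 2n}.

Reconstruction N_k = L_k + up(N_{k+1}) is exact by construction (float
round-off only; the suite verifies < 1e-5 relative error).  The pyramid is
computed on the preprocessed (resampled, z-scored) T1 channel so level
magnitudes are comparable across cases.  The network consumes levels L₀ and
L₁; the builder accepts any K for analysis.

## Edge attention and fusion

* CBAM: channel gate (global average and max pooling through a shared
  two-layer MLP, reduction 16 capped so the hidden width is ≥ 1) then
  spatial gate (7×7×7 convolution over the channel-mean and channel-max
  maps).  The two branches of each LEA block have separate CBAM weights —
  they attend to different feature statistics.
* λ is one unconstrained trainable scalar per LEA block, initialised 0.5;
  β = 1 − λ is structural, and nothing clamps λ to [0, 1] since the mixing
  rule does not require it.
* The sigmoid in the LEA gating is applied to the raw concatenation
  [f_l, f_map] before the 1×1×1 projection — implemented exactly as
  specified even though gating after the projection would be more
  conventional.
* In MFF(2), the downsampling of f_edge¹ is plain stride-2 subsampling
  (no Gaussian pre-smoothing — deliberately different from the smoothed
  decimation inside the high-frequency residual M^i), the bridge conv lifts
  C → 2C, and the gate conv I preserves 2C.  MFF(2) executes before MFF(1):
  the decoder reaches the half-resolution layer first; the numbering is by
  resolution.
* Fusion is plain addition f_d^i + f_mff^i with no renormalisation, so
  forcing the fused features to zero reproduces the plain backbone
  bit-exactly (asserted in the suite).
* The T1 branch mirrors the main encoder's first two stages (stem, stage-1
  blocks, down block, stage-2 blocks) with the same B/R but independent
  weights, and is trained jointly end to end.

## Loss

`L = Σ_i w_dice^i·L_Dice(f_DS^i, f^i) + w_ce^i·L_CE(f_DS^i, f^i)` over the
five supervised levels.  Soft Dice uses the squared-denominator form
2Σpg / (Σp² + Σg²) with smoothing 1e-5 in numerator and denominator,
averaged over foreground classes; for exactly binary probabilities it
reduces to the voxel-count Dice.  Cross entropy is the mean voxel negative
log-likelihood.  Ground truth is downsampled per level by nearest neighbour
keeping voxels (0, 2, 4, ...), aligned with the encoder's stride-2
convention.  Level weights halve with depth and are normalised to sum 1,
with Dice and CE weights equal — the usual deep-supervision convention for
this family of networks.

## Evaluation methodology

* Overlap: DC, precision, recall, IoU from voxel counts.  Empty-mask
  conventions: DC(∅,∅) = IoU(∅,∅) = 1 (preserving DC = 2·IoU/(1+IoU));
  precision/recall with 0/0 denominators are 0.  Recorded per case so
  cohort averages are reproducible.
* HD95: 95th percentile (linear interpolation) of nearest-neighbour
  distances between all foreground voxel centres in mm, symmetrised by the
  outer max; undefined (and excluded from averages) when either mask is
  empty.  Voxel centres, not extracted surfaces: the definition is over
  point sets.
* Clusters: maximal 26-connected components; a GT component with any
  predicted overlap is a detected (TP) lesion, with none an FN lesion; a
  predicted component with no GT overlap is an FP lesion.
* Detection rates: 100·N_d/N_a with N_d the cases whose DC strictly
  exceeds the threshold (0.0 = "one-voxel overlap", and 0.22).  Slice
  rates: per axis, the detected fraction of GT-bearing slices (2D DC above
  threshold), averaged unweighted over the three axes.  Slices without GT
  are excluded from the denominator — the alternative (all slices) would
  conflate detection with specificity.
* Post-processing: keep only the largest 26-connected predicted component
  iff that strictly improves the case DC, else keep the prediction
  unchanged (ties on size broken by lowest label).  Applied per case; by
  construction it never lowers DC.

## Data pipeline

Preprocessing: joint nonzero bounding-box crop → resample to 1 mm isotropic
(trilinear for images, nearest for masks) → per-modality z-score over
nonzero voxels with background kept at zero → centre pad/crop to 128³
(configurable, divisible by 16).  Each step is recorded in an inverse
transform so predictions map back to the native grid.  NIfTI volumes are
reoriented to closest-canonical axes on load.  Five-fold cross-validation
splits are a seeded permutation dealt round-robin.

## Synthetic phantoms

The generator emulates the salient difficulties of the clinical data: an
ellipsoidal head holding two smoothly interleaved tissue compartments
(intensities 1.0/1.4 from a thresholded smoothed Gaussian field, smoothness
4 voxels), one ellipsoidal lesion per case (semi-axes 4–12 voxels at 128³;
the clinical cohorts average one annotated lesion per patient) whose
boundary is blurred with σ = 1.5 mm, modality-specific additive contrasts
(T1 −0.3, FLAIR +0.8, PET −0.6 relative to the 0.4 tissue gap) and Gaussian
noise (sd 0.1).  Ground truth is the pre-blur ellipsoid support; lesion
volume is bounded below 2% of the head.  Cases are bit-deterministic per
seed.

What the phantoms do **not** model: cortical geometry and the grey/white
junction, partial-volume effects, acquisition artefacts, inter-subject
anatomy, registration error, or multi-focal disease.  Tests passing on
phantoms therefore establish the correctness of the machinery (shapes,
gradients, losses, metrics, reproducibility) and that the network can learn
blurred-edge low-contrast targets — they do not establish clinical
segmentation accuracy.

## Scaled-down experiments

Problem sizes were chosen so each experiment runs in minutes on one core:
the learning check fits the tiny configuration (C = 8, one block per stage)
to a single 32³ phantom with AdamW (lr 1e-3, defaults otherwise, batch 1)
for at most 300 steps, evaluating training Dice every 50 steps and stopping
once it exceeds 0.9.  The fusion-off identity and oracle comparisons use
16³ inputs and 12³ masks respectively.  Whole-volume (no patching)
training is the default at these sizes; there is no data augmentation, so
runs are exactly seeded.

## Numerical choices and degenerate inputs

* float32 parameters and activations; normalisation eps 1e-5; cross-entropy
  log guard 1e-12.
* He-style initialisation, biases zero; parameters are a deterministic
  function of (architecture, seed) via a single generator consumed in
  construction order.
* AdamW: betas (0.9, 0.999), eps 1e-8, decoupled weight decay 0.01,
  constant learning rate (no schedule by default).
* Convolution gradients are hand-written VJPs (validated against finite
  differences in the suite); depthwise-conv biases legitimately receive
  zero gradient because the following per-channel normalisation cancels
  them.
* Grids must be divisible by 16 (four 2× downsamplings); upsampling always
  receives an explicit target shape so odd sizes round-trip exactly in the
  pyramid API.
* Empty predictions pass through post-processing unchanged; empty cohorts
  are rejected rather than returning NaN rates.

## Known limitations

* Batch norm uses current-batch statistics at inference (see above).
* The CPU implementation is practical at experiment scale (32³–64³, tiny
  configuration); full 128³ M-size training is out of reach without an
  accelerated backend, so headline clinical-scale accuracy is not
  reproduced here.
* The checkpoint format stores parameters only; resuming restarts optimiser
  moments.
* λ initialisation is exposed (`LEAConfig.lambda_init`) but the package
  does not re-run the initialisation sweep; 0.5 is the default.
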