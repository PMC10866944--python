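# Methods

## Problem and scope

`gliomaseg` segments glioma sub-regions from multimodal brain MRI (T1, T1Gd,
T2, FLAIR) using a 2D hybrid CNN–Transformer network, and explains the
trained model post hoc with Grad-CAM saliency.  Inputs follow the BraTS
convention: co-registered, skull-stripped, 1 mm isotropic volumes with an
integer label map over {0, 1, 2, 4} (background, necrotic/non-enhancing
core, peritumoral edema, enhancing tumor).  Evaluation uses the nested
composite regions ET = {4}, TC = {1, 4}, WT = {1, 2, 4} with Dice similarity
and the 95th-percentile surface distance (HD95).

Upstream harmonization (resampling, registration, skull-stripping) is
assumed done; DICOM ingestion, bias-field correction and 3D model variants
are out of scope.

## Preprocessing

Per case: (1) non-brain voxels are forced to exactly zero — the brain mask
is the union of nonzero voxels across channels with connected components
smaller than 1% of the largest removed, which makes the operation idempotent
and robust to speckle; (2) each channel is z-scored over brain voxels of the
whole 3D volume using the *population* standard deviation (the convention is
fixed so exact tests are possible; the choice between population and sample
std is otherwise immaterial); (3) the in-plane field of view is
center-cropped to 192×192 (geometric array center, zero-padding when the
input is smaller — padding is recorded as negative crop offsets); (4) axial
slices are taken along the third axis after reorienting every volume to RAS.
All geometry is recorded in a `PreprocRecord`, and the label pipeline
volume → slices → reassembled volume → inverse crop is exactly invertible.

Whether z-score statistics should use brain voxels only or all voxels is
ambiguous in the BraTS literature; brain-only is used here because the
background has just been forced to zero and would only dilute the
statistics.  A constant channel falls back to std = 1 and is flagged.

## Network

A U-shaped encoder–decoder with a vision-transformer bottleneck:

- **Encoder** — four double-conv blocks ([conv3×3 → BN → ReLU] ×2) with
  channel widths K, 2K, 4K, 8K (default K = 32) and three 2×2 max-poolings,
  giving an H/8 × W/8 bottleneck (24×24 for 192×192 inputs).  Per-level
  channel doubling is the U-Net convention; only K and the /8 factor are
  fixed by the architecture description.
- **Bottleneck** — features are tokenized per P×P patch (default P = 1, one
  token per position), linearly embedded to `embed_dim` = 256 with learned
  1D positional embeddings, and passed through L = 4 pre-norm transformer
  blocks: z′ = MSA(LN(z)) + z, z = MLP(LN(z′)) + z′, with 8 heads and an MLP
  width of 1024.  Layer norm lives only inside the transformer; batch norm
  only in conv blocks.
- **Feature restoration** — tokens are reshaped back to the spatial grid and
  projected to the decoder entry width by a learned linear map (exactly a
  1×1 convolution for P = 1; a learned pixel-shuffle for P > 1).
- **Decoder** — a double-conv block at bottleneck resolution, then three
  2×2-stride-2 transposed convolutions, each followed by concatenation of
  the matching encoder skip and a double-conv block; a 1×1 convolution and
  per-pixel softmax give the 4-class probability map.  This yields 8 conv
  blocks total (4 encoder + 4 decoder).

Weight init: He-normal for convolutions, truncated normal (std 0.02) for
transformer projections.  The classifier head uses a truncated normal with
std 0.3: large enough to break the class tie (a near-zero head makes
cross-entropy collapse the prediction to background before the dice term
can act — dice gradients vanish with the softmax probability of the rare
classes), small enough that the untrained network is near-uniform and the
initial loss matches ln C + L_GD(uniform) closely.

`ModelConfig.head_bias_prior` optionally initializes the head bias at the
log class frequencies (the detection-head "prior bias" trick).  Starting the
prediction at the class prior removes the large early cross-entropy pull
toward all-background — empirically, on highly imbalanced data a sizable
fraction of random inits otherwise falls into a slow background-collapse
basin.  The option is off by default (zero bias, near-uniform start) and on
in the desk-scale study configuration.

Internal layers are tagged EB1–EB4, BOT, DB1–DB4, OUT for the saliency
generator.

### Autodiff engine

No tensor/autodiff framework is part of the dependency set; the package
ships a compact reverse-mode autodiff engine on numpy (`gliomaseg.nn`):
a Tensor tape with elementwise/reduction/matmul primitives plus layer-level
primitives (im2col convolution, 2×2 max-pool, 2×2-stride-2 transposed
convolution).  Batch norm, layer norm and attention are differentiated by
composition, so their gradients are correct by construction; every primitive
and module is tested against central finite differences.  All training math
is float32; float64 inputs are honored for oracle tests.

## Objective

L_overall = L_GD + L_CE with

- generalized dice: L_GD = 1 − (2 Σ_c W_c Σ_n y s + ε)/(Σ_c W_c (Σ_n y + Σ_n s) + ε),
  W_c = 1/(Σ_n y_c + ε_w)², ε = ε_w = 1e-5.  The inverse-squared-volume
  weights counter the foreground/background imbalance.  Class sums are
  pooled over the whole batch rather than averaged per sample — this
  stabilizes W_c for classes present in only a few slices of a batch.
- categorical cross-entropy: mean over pixels of −Σ_c y_c log s_c with a
  1e-7 probability floor inside the log.

The denominator of the dice term is read as Σy + Σs (the standard
generalized-dice form).

## Metrics

DSC = 2|P∩T|/(|P|+|T|), with 1 for two empty masks.  HD95 takes surface
voxels (mask minus its 6-connected erosion), computes nearest-surface
distances in both directions via exact Euclidean distance transforms with
anisotropic spacing, pools both directions and takes one 95th percentile
(`hd95_mode="pooled"`; `"max_directed"` — the max of per-direction 95th
percentiles used by some BraTS tooling — is available).  One empty mask
returns a sentinel (default: the image diagonal in mm); two empty masks
return 0.

## Training

SGD with momentum 0.9 and a constant learning rate of 8e-3 (only the initial
value is specified by the recipe; no schedule is applied), batch size 16,
case-level k-fold cross-validation (k = 5 by default) with per-epoch
reshuffling.  All retained slices (≥1% nonzero pixels) are visited once per
epoch.  Per-epoch RNG streams derive from (global seed, fold, epoch) so runs
are reproducible and resumable.  The best checkpoint per fold is selected by
validation whole-tumor dice (the selection rule is this package's choice).
A NaN loss aborts with batch statistics.

**Random restarts.**  At desk scale a minority of random initializations
converges to a local optimum that segments the heavily dice-weighted rare
classes but never picks up edema (whose generalized-dice weight is orders
of magnitude smaller, leaving it to the slow cross-entropy signal).  The
trainer therefore supports a bounded restart policy: if the best validation
whole-tumor dice is still below `stall_threshold` (default 0.7) after
`stall_check_fraction` (default 2/3) of the epochs, the model is
reinitialized from a new derived seed and training restarts; restart events
are logged.  The policy is off by default and enabled (2 restarts) in the
desk-scale study, where a single restart empirically rescues every stalled
run observed.  The whole procedure remains deterministic for a fixed seed.

Augmentation (applied jointly to image and label of each slice):
horizontal/vertical flips (p = 0.5 per axis), shifts up to 10% of the image
size per axis (the shift range is not specified anywhere; 10% is this
package's default and is configurable), rotation with magnitude U(0, 20)°
and random sign, zoom U(0.8, 1.2), multiplicative brightness U(0.8, 1.2)
(the "20% deviation" is read as multiplicative on z-scored intensities),
Gaussian noise with std 0.01 in normalized units.  Geometric transforms use
bilinear interpolation for images and nearest neighbor for labels;
out-of-frame regions are filled with the background value 0.

## Ensembling

The k fold models' label volumes are fused with STAPLE.  Binary STAPLE runs
one-vs-rest per tumor label: EM alternates the voxel posterior of the latent
true segmentation with per-rater sensitivity/specificity updates, iterating
to |Δp|+|Δq| < 1e-7 or 100 iterations (non-convergence returns a flagged
result with a warning).  Initialization p = q = 0.99999; the prior is the
per-voxel mean of the rater masks (a scalar prior is accepted, but with few
raters — two folds in particular — a low scalar prior makes the EM converge
to the raters' intersection, a systematic under-segmentation; the spatial
prior anchors the posterior at agreement regions and lets the estimated
rater performances resolve disagreements).  A voxel gets the label with the
highest posterior when it exceeds the implied background posterior, with
deterministic tie-break priority 4 > 1 > 2.  EM runs inside the bounding box
of rater-positive voxels — outside it all raters agree on background, so the
result is identical and the problem smaller.  Whether to fuse hard labels or
soft probabilities is not specified by the recipe; hard one-vs-rest fusion
is the common practice and is what ships.

## Explainability

Grad-CAM: for a scalar class score y^c, α_l^c is the spatial mean of
∂y^c/∂A^l and the map is ReLU(Σ_l α_l^c A^l), bilinearly upsampled to the
input grid and min-max normalized (all-zero maps are kept all-zero and
flagged).  For dense segmentation y^c has no canonical definition; the
default sums the class-c pre-softmax score over pixels *predicted* as c
(falling back to all pixels when the class is absent), with all-pixel and
ROI-masked variants exposed.  Explanation generation never mutates weights.

The modality-ablation experiment zeroes input channels at inference time
(zero is the background value after z-scoring) in both keep-only and
leave-one-out directions and records per-region dice.  Retraining-based
ablation is out of scope.

## Synthetic phantoms

Phantoms make the pipeline testable without clinical data: an ellipsoidal
brain (white matter core, gray-matter shell) in an exactly-zero background,
with a nested spherical tumor — necrotic core (label 1), enhancing rim
(label 4), edema shell (label 2) — and i.i.d. Gaussian intensity noise
(default std 0.05 against minimum inter-tissue contrast gaps of ~0.2).
The contrast table plants the radiological signature of high-grade glioma:
edema bright on FLAIR/T2 but *identical to white matter* on T1/T1Gd, the
enhancing rim brightest on T1Gd, the necrotic core dark on T1Gd.  Because
edema is separable only through FLAIR/T2, modality attribution has a planted
ground truth.  Default geometry is 96×96×32 voxels with brain semi-axes
(40, 40, 14) and tumor radii 10/6.5/3.5 — small enough for CPU training,
large enough to exercise both the crop and the pad branch of preprocessing.

What phantoms do *not* model: real anatomy and texture, bias fields, Rician
noise, multi-focal or infiltrative growth, inter-scanner variation.  Passing
the phantom-scale tests demonstrates that the pipeline's machinery (losses,
training loop, fusion, attribution) is correct and learnable, not that the
network reaches clinical-grade accuracy on real BraTS data — that requires
the full-size configuration, the real cohort and long GPU training.

## Desk-scale study sizes

The test suite and the acceptance script run a scaled-down study chosen as
this package's reference configuration for CPU execution: 6 phantom cases,
2 folds, a K = 8 / L = 1 / 64-dim model on 96×96 slices, 18 epochs, batch
size 8, with the head-bias prior enabled (batch 8 doubles the SGD step
count per epoch at equal compute, which together with the prior bias makes
the escape from the background-collapse basin reliable across seeds).
Under these conditions validation whole-tumor dice reliably exceeds 0.95
and STAPLE fusion does not fall more than 0.02 below the best fold.  The
CLI smoke chain uses an even smaller 48×48×16 phantom with a 32×32 crop.

## Numerical choices

- float32 model math; losses follow the caller's precision.
- Probability floor 1e-7 in the log; ε = 1e-5 in the dice term.
- Softmax is computed with max-subtraction; attention scores likewise.
- Batch-norm eval mode uses running statistics (momentum 0.1), making
  inference deterministic.
- `np.percentile` linear interpolation defines the 95th percentile of HD95.
- Deterministic tie-breaks: argmax takes the lowest index (class order
  background, 1, 2, 4); STAPLE ties resolve 4 > 1 > 2.

## Known limitations

- The 2D slice model has no through-plane context; stacked predictions can
  be inconsistent along the axial axis.
- One-vs-rest STAPLE ignores inter-label exclusivity during EM; labels
  compete only at the final argmax.
- The numpy engine trains desk-scale models in minutes but is not suited to
  the full 240×240×155 cohort at K = 32 — that configuration is exposed and
  tested for contracts (shapes, softmax normalization, gradients), not
  trained to convergence here.
- Grad-CAM for near-perfectly-confident predictions can produce very sparse
  gradients; the all-zero map flag marks degenerate cases.
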