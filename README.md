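# gliomaseg

Hybrid CNN–Transformer segmentation of glioma sub-regions from multimodal
brain MRI, with post-hoc Grad-CAM explanations of what the network looked
at — and a synthetic phantom generator so the entire pipeline can be built,
trained and tested on a laptop without access to clinical data.

**Who it is for.** Researchers working on brain-tumor segmentation who want
a self-contained, inspectable reference implementation of the
U-Net-with-ViT-bottleneck family, its class-imbalance-aware training
objective, STAPLE ensembling of cross-validation folds, and
saliency/modality-attribution analysis of the trained model.

## The model

Cases follow the BraTS convention: four co-registered, skull-stripped
volumes (T1, T1Gd, T2, FLAIR) and labels 1 (necrotic/non-enhancing core),
2 (peritumoral edema), 4 (enhancing tumor).  Evaluation uses the nested
regions ET = {4} ⊆ TC = {1,4} ⊆ WT = {1,2,4} with Dice
(DSC = 2|P∩T|/(|P|+|T|)) and the 95th-percentile surface distance (HD95).

The network is a 2D U-shaped encoder–decoder whose bottleneck is a stack of
pre-norm vision-transformer blocks

    z′_ℓ = MSA(LN(z_{ℓ−1})) + z_{ℓ−1}
    z_ℓ  = MLP(LN(z′_ℓ)) + z′_ℓ

operating on tokens taken from the H/8 × W/8 convolutional feature grid
(double-conv blocks with widths K, 2K, 4K, 8K; K = 32 by default).  Decoding
uses 2×2 transposed convolutions with encoder skip concatenation and ends
in a per-pixel 4-class softmax.  Training minimizes

    L = L_GD + L_CE,   L_GD = 1 − (2 Σ_c W_c Σ_n y s + ε)/(Σ_c W_c (Σ_n y + Σ_n s) + ε)

with inverse-squared-volume class weights W_c = 1/(Σ_n y_c)², under SGD
(momentum 0.9, lr 8e-3), case-level k-fold cross-validation, on-the-fly
augmentation (flips, shifts, ±20° rotation, ±20% zoom, ±20% brightness,
σ = 0.01 Gaussian noise), and STAPLE (EM) fusion of the fold models.
Grad-CAM maps ReLU(Σ_l α_l^c A^l) with α_l^c the spatial mean of ∂y^c/∂A^l
are available at every tagged layer (EB1–EB4, BOT, DB1–DB4, OUT), plus a
keep-one / leave-one-out modality-ablation experiment.

There is no external deep-learning framework dependency: `gliomaseg.nn` is
a compact numpy reverse-mode autodiff engine (im2col convolutions, pooling,
transposed convolutions, batch/layer norm, multi-head attention, SGD),
verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from gliomaseg.phantom import PhantomSpec, generate_case
from gliomaseg.brats_io import derive_regions
from gliomaseg.objective import overall_loss, one_hot, dsc, hd95
from gliomaseg.staple import staple_multilabel

spec = PhantomSpec(seed=7)                 # synthetic case, known truth
vol, lab = generate_case(spec)
print("volume shape:", vol.shape, "| spacing:", vol.spacing)
regions = derive_regions(lab.labels)
print("region voxels  ET/TC/WT:",
      int(regions.ET.sum()), int(regions.TC.sum()), int(regions.WT.sum()))

y = one_hot(np.random.default_rng(0).integers(0, 4, size=(8, 8)))
terms = overall_loss(np.full_like(y, 0.25), y)   # uniform prediction
print(f"uniform prediction: L_GD={terms.gd:.4f}  L_CE={terms.ce:.4f}  "
      f"L_Overall={terms.overall:.4f}  (ln 4 = {np.log(4):.4f})")

raters = []                                # three imperfect "fold models"
rng = np.random.default_rng(1)
for _ in range(3):
    noisy = lab.labels.copy()
    noisy[rng.random(noisy.shape) > 0.995] = 0
    raters.append(noisy)
fused, perf = staple_multilabel(raters)
wt_1 = dsc(derive_regions(raters[0]).WT, regions.WT)
wt_f = dsc(derive_regions(fused).WT, regions.WT)
print(f"single-rater WT dice {wt_1:.4f} -> STAPLE consensus WT dice {wt_f:.4f}")
print(f"consensus WT HD95: "
      f"{hd95(derive_regions(fused).WT, regions.WT, spacing=vol.spacing):.2f} mm")
```

Output:

```
volume shape: (96, 96, 32) | spacing: (1.0, 1.0, 1.0)
region voxels  ET/TC/WT: 928 1088 4224
uniform prediction: L_GD=0.7578  L_CE=1.3863  L_Overall=2.1441  (ln 4 = 1.3863)
single-rater WT dice 0.9964 -> STAPLE consensus WT dice 1.0000
consensus WT HD95: 0.00 mm
```

The uniform prediction scores L_CE = ln 4 exactly (four equiprobable
classes) plus a generalized-dice penalty; the STAPLE consensus of three
raters with independent dropout noise recovers the exact ground truth
(dice 1.0, HD95 0 mm) even though each single rater is imperfect.

## Command-line pipeline

```bash
gliomaseg simulate   --out-dir cases --n 6                 # phantom cohort
gliomaseg preprocess --data-dir cases --out-dir prep
gliomaseg train      --config cfg.yaml --data-dir cases --out-dir model
gliomaseg predict    --checkpoint model/fold0.npz --case cases/phantom_000 --out pred0.nii.gz
gliomaseg ensemble   --inputs pred0.nii.gz --inputs pred1.nii.gz --out fused.nii.gz
gliomaseg evaluate   --pred fused.nii.gz --truth-dir cases --out eval.csv
gliomaseg explain    --checkpoint model/fold0.npz --case cases/phantom_000 \
                     --layer OUT --target ET --out heatmap.nii.gz
```

All subcommands log JSON lines, stamp every artifact directory with the
resolved configuration, and are deterministic for a fixed `--seed`.

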