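"""Case-level k-fold cross-validation training and volume-level inference.

Training follows the published recipe: SGD with momentum 0.9 and constant
learning rate 8e-3, batches of 16 axial slices, per-epoch reshuffling, the
generalized-dice + cross-entropy objective, and on-the-fly augmentation.
Folds are split at case level (never slice level), so no validation case
contributes any training slice.  The best checkpoint per fold is selected
by validation whole-tumor dice.

Inference runs every axial slice of a preprocessed volume through the 2D
network, stacks the class probabilities, argmax-decodes to BraTS labels and
maps the result back onto the original volume grid via the preprocessing
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, augment_pair
from .brats_io import LabelVolume, MultimodalVolume, derive_regions, indices_to_labels, labels_to_class_indices
from .net import HybridSegNet, ModelConfig, build_model, save_checkpoint
from .nn import SGD, Tensor, no_grad
from .objective import dsc, one_hot, overall_loss
from .preprocess import (
    PreprocRecord,
    SlicePair,
    extract_axial_slices,
    filter_slices,
    invert_crop,
    preprocess_case,
)


@dataclass
class TrainConfig:
    lr: float = 8e-3
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 250
    folds: int = 5
    seed: int = 0
    min_brain_fraction: float = 0.01
    val_interval: int = 5
    crop_size: tuple[int, int] = (192, 192)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    #: random-restart policy: if the best validation WT dice is still below
    #: ``stall_threshold`` after ``stall_check_fraction`` of the epochs, the
    #: model is reinitialized (new derived seed) and training restarts.
    #: A small fraction of random inits otherwise converges to a poor
    #: local optimum that never picks up the under-weighted edema class.
    #: 0 restarts disables the policy.
    max_restarts: int = 0
    stall_threshold: float = 0.7
    stall_check_fraction: float = 0.67

    def __post_init__(self):
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1 or self.lr <= 0:
            raise ValueError("batch_size must be >= 1 and lr > 0")


def make_folds(case_ids: list[str], k: int, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Deterministic case-level k-fold split: list of (train_ids, val_ids)."""
    ids = list(case_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} cases for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    chunks = [list(c) for c in np.array_split(perm, k)]
    return [(sorted(x for j, c in enumerate(chunks) for x in c if j != i), sorted(chunks[i]))
            for i in range(k)]


def _epoch_seed(global_seed: int, fold: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((global_seed, fold, epoch)))


@dataclass
class TrainResult:
    model: HybridSegNet
    log: list[dict]
    best_val_wt_dice: float
    best_epoch: int
    sample_order: list[list[int]] = field(default_factory=list)  # per-epoch slice order


def _batch_arrays(pairs: list[SlicePair], num_classes: int) -> tuple[Tensor, np.ndarray]:
    imgs = np.stack([p.image for p in pairs]).transpose(0, 3, 1, 2)  # N,C,H,W
    labs = np.stack([labels_to_class_indices(p.label) for p in pairs])
    return Tensor(imgs.astype(np.float32)), one_hot(labs, num_classes)


def train_fold(
    cases: dict[str, tuple[MultimodalVolume, LabelVolume]],
    train_ids: list[str],
    val_ids: list[str],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    fold: int = 0,
    out_dir: Path | str | None = None,
) -> TrainResult:
    """Train one fold model on preprocessed slices of the training cases."""
    overlap = set(train_ids) & set(val_ids)
    if overlap:
        raise ValueError(f"cases in both train and validation sets: {sorted(overlap)}")
    prep: dict[str, tuple] = {}
    for cid in list(train_ids) + list(val_ids):
        vol, lab = cases[cid]
        pvol, plab, rec = preprocess_case(vol, lab, crop_size=cfg.crop_size)
        prep[cid] = (pvol, plab, rec)
    train_slices: list[SlicePair] = []
    for cid in train_ids:
        pvol, plab, _ = prep[cid]
        train_slices += filter_slices(extract_axial_slices(pvol, plab), cfg.min_brain_fraction)
    if not train_slices:
        raise ValueError("no training slices left after brain-content filtering")

    log: list[dict] = []
    best = {"dice": -1.0, "epoch": -1, "state": None}
    sample_order: list[list[int]] = []
    step = 0
    stall_epoch = max(0, int(np.ceil(cfg.stall_check_fraction * cfg.epochs)) - 1)
    attempt = 0
    while True:
        seed_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, fold, 9999, attempt)))
        model = build_model(model_cfg, seed=int(seed_rng.integers(0, 2**31 - 1)))
        opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
        best = {"dice": -1.0, "epoch": -1, "state": None}
        sample_order = []
        stalled = False
        for epoch in range(cfg.epochs):
            rng = _epoch_seed(cfg.seed, fold, epoch)
            order = rng.permutation(len(train_slices))
            sample_order.append([int(i) for i in order])
            model.train()
            for start in range(0, len(order), cfg.batch_size):
                batch_idx = order[start:start + cfg.batch_size]
                pairs = [augment_pair(train_slices[i], cfg.augment, rng)[0] for i in batch_idx]
                x, y_idx = _batch_arrays(pairs, model_cfg.num_classes)
                probs = model(x)  # N,C,H,W
                terms = overall_loss(probs.transpose((0, 2, 3, 1)), y_idx)
                if not np.isfinite(terms.overall):
                    stats = {"batch_mean": float(x.data.mean()), "batch_std": float(x.data.std()),
                             "gd": terms.gd, "ce": terms.ce}
                    raise RuntimeError(f"non-finite loss at epoch {epoch} step {step}: {stats}")
                opt.zero_grad()
                terms.tensor.backward()
                opt.step()
                log.append({"epoch": epoch, "step": step, "L_GD": terms.gd,
                            "L_CE": terms.ce, "L_Overall": terms.overall})
                step += 1
            last_epoch = epoch == cfg.epochs - 1
            if val_ids and (epoch % cfg.val_interval == cfg.val_interval - 1 or last_epoch):
                wt = _validate(model, prep, val_ids)
                log.append({"epoch": epoch, "step": step, "val_wt_dice": wt})
                if wt > best["dice"]:
                    best = {"dice": wt, "epoch": epoch, "state": model.state_dict()}
            if (val_ids and attempt < cfg.max_restarts and epoch >= stall_epoch
                    and best["dice"] >= 0 and best["dice"] < cfg.stall_threshold):
                log.append({"epoch": epoch, "step": step, "restart": attempt + 1,
                            "stalled_at_dice": best["dice"]})
                stalled = True
                break
        if not stalled:
            break
        attempt += 1
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / f"fold{fold}.npz",
                        extra={"fold": fold, "best_epoch": best["epoch"],
                               "best_val_wt_dice": best["dice"]})
        _write_log_csv(log, out_dir / f"fold{fold}_log.csv")
    return TrainResult(model=model, log=log, best_val_wt_dice=best["dice"],
                       best_epoch=best["epoch"], sample_order=sample_order)


def _write_log_csv(log: list[dict], path: Path):
    import csv

    keys = ["epoch", "step", "L_GD", "L_CE", "L_Overall", "val_wt_dice"]
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=keys)
        wr.writeheader()
        for row in log:
            wr.writerow({k: row.get(k, "") for k in keys})


def _validate(model: HybridSegNet, prep: dict, val_ids: list[str]) -> float:
    """Mean whole-tumor dice over validation cases (on the cropped grid)."""
    model.eval()
    dices = []
    for cid in val_ids:
        pvol, plab, _ = prep[cid]
        pred = _predict_cropped(model, pvol)
        dices.append(dsc(derive_regions(pred).WT, derive_regions(plab.labels).WT))
    return float(np.mean(dices))


def _predict_cropped(model: HybridSegNet, pvol: MultimodalVolume, batch: int = 16,
                     return_probs: bool = False):
    """Predict labels on the preprocessed (cropped) grid, slice by slice."""
    slices = extract_axial_slices(pvol)
    probs = []
    with no_grad():
        for start in range(0, len(slices), batch):
            chunk = slices[start:start + batch]
            x = Tensor(np.stack([s.image for s in chunk]).transpose(0, 3, 1, 2))
            p = model(x).data  # N,C,H,W
            probs.append(p.transpose(0, 2, 3, 1))  # N,H,W,C
    prob = np.concatenate(probs, axis=0).transpose(1, 2, 0, 3)  # H,W,D,C
    labels = indices_to_labels(prob.argmax(axis=-1))
    if return_probs:
        return labels, prob
    return labels


def predict_volume(
    model: HybridSegNet,
    vol: MultimodalVolume,
    crop_size: tuple[int, int] = (192, 192),
) -> tuple[LabelVolume, np.ndarray, PreprocRecord]:
    """Segment a raw case: preprocess, slice, forward, reassemble, un-crop.

    Returns the label volume on the original grid, the per-class probability
    volume (H, W, D, C, background-filled outside the crop window), and the
    preprocessing record.
    """
    pvol, _, rec = preprocess_case(vol, None, crop_size=crop_size)
    labels_c, prob_c = _predict_cropped(model, pvol, return_probs=True)
    labels = invert_crop(labels_c, rec, fill=0)
    num_classes = prob_c.shape[-1]
    background = np.zeros(num_classes, dtype=prob_c.dtype)
    background[0] = 1.0
    prob = np.stack([invert_crop(prob_c[..., c], rec, fill=background[c])
                     for c in range(num_classes)], axis=-1)
    return LabelVolume(labels.astype(np.int16), vol.affine, vol.spacing), prob, rec
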