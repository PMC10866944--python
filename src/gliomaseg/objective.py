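"""Training objective (generalized dice + categorical cross-entropy) and metrics.

The loss is L_overall = L_GD + L_CE.  The generalized dice term weights each
class c by W_c = 1 / (Σ_n y_nc)^2 (guarded by a small epsilon), which
counters the extreme foreground/background imbalance of glioma segmentation:

    L_GD = 1 - (2 Σ_c W_c Σ_n y_nc s_nc + ε) / (Σ_c W_c (Σ_n y_nc + Σ_n s_nc) + ε)

with s the softmax prediction and y the one-hot target.  Class sums are
pooled over the whole batch, which stabilizes W for classes that appear in
only a few slices of a batch.

Evaluation metrics are the BraTS pair: Dice similarity coefficient and the
95th-percentile symmetric surface distance (HD95, pooled-direction
convention by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor

EPSILON = 1e-5
WEIGHT_EPSILON = 1e-5
PROB_FLOOR = 1e-7


@dataclass
class LossTerms:
    gd: float
    ce: float
    overall: float
    class_weights: np.ndarray
    tensor: Tensor | None = None  # differentiable overall loss, when built on the tape


def _as_tensor(x) -> Tensor:
    # keep the caller's float precision (float64 toys stay float64)
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def one_hot(indices: np.ndarray, num_classes: int = 4) -> np.ndarray:
    """Class-index array -> trailing one-hot axis."""
    idx = np.asarray(indices)
    out = np.zeros(idx.shape + (num_classes,), dtype=np.float32)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


def _flatten_cls(t: Tensor) -> Tensor:
    """(..., C) -> (N, C) with N the pooled pixel count."""
    c = t.shape[-1]
    return t.reshape(-1, c)


def generalized_dice_loss(s, y, eps: float = EPSILON) -> tuple[Tensor, np.ndarray]:
    """Generalized dice loss with inverse-squared-volume class weights.

    W_c = 1/(Σ_n y_nc + ε_w)² for classes present in the batch; a class with
    no target voxels gets weight 0 — otherwise its near-infinite weight
    dominates the denominator and destabilizes training whenever a rare
    class misses a batch.  Weights are treated as constants (not
    differentiated through).

    Returns the scalar loss tensor and the per-class weights.
    """
    s, y = _as_tensor(s), _as_tensor(y)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: s {s.shape} vs y {y.shape}")
    sf, yf = _flatten_cls(s), _flatten_cls(y)
    ysum = yf.data.sum(axis=0)                 # Σ_n y_nc, per class (constant)
    w = np.where(ysum > 0, (ysum + WEIGHT_EPSILON) ** -2.0, 0.0)
    w_det = Tensor(w)
    inter = (yf * sf).sum(axis=0)
    num = 2.0 * (w_det * inter).sum() + eps
    den = (w_det * (Tensor(ysum) + sf.sum(axis=0))).sum() + eps
    loss = 1.0 - num / den
    return loss, w.copy()


def categorical_cross_entropy(s, y, floor: float = PROB_FLOOR) -> Tensor:
    """Mean over pixels of -Σ_c y_c log s_c, with a probability floor."""
    s, y = _as_tensor(s), _as_tensor(y)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: s {s.shape} vs y {y.shape}")
    sf, yf = _flatten_cls(s), _flatten_cls(y)
    n = sf.shape[0]
    return -(yf * sf.clip_min(floor).log()).sum() * (1.0 / n)


def overall_loss(s, y, eps: float = EPSILON) -> LossTerms:
    """L_overall = L_GD + L_CE; all three terms reported."""
    gd, w = generalized_dice_loss(s, y, eps)
    ce = categorical_cross_entropy(s, y)
    total = gd + ce
    return LossTerms(gd=float(gd.data), ce=float(ce.data), overall=float(total.data),
                     class_weights=w, tensor=total)


# ------------------------------------------------------------------- metrics
def dsc(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice similarity coefficient; both masks empty -> 1 by convention."""
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(true_mask, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def _surface(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: mask minus its erosion (isolated voxels are their own surface)."""
    er = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(mask.ndim, 1), border_value=0)
    return mask & ~er


def hd95(
    pred_mask: np.ndarray,
    true_mask: np.ndarray,
    spacing=None,
    mode: str = "pooled",
    empty_sentinel: float | None = None,
) -> float:
    """95th-percentile surface distance in mm.

    ``mode='pooled'`` pools both direction's surface-to-surface nearest
    distances and takes one 95th percentile; ``mode='max_directed'`` takes
    the max of the two per-direction 95th percentiles (BraTS tooling
    convention).  One empty mask returns the sentinel (default: the image
    diagonal in mm); two empty masks return 0.
    """
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(true_mask, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    spacing = np.ones(p.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    if not p.any() and not t.any():
        return 0.0
    if not p.any() or not t.any():
        if empty_sentinel is not None:
            return float(empty_sentinel)
        return float(np.linalg.norm(np.array(p.shape) * spacing))
    sp, st = _surface(p), _surface(t)
    # distance from every voxel to the nearest surface voxel of the other mask
    dt_t = ndimage.distance_transform_edt(~st, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    d_p_to_t = dt_t[sp]
    d_t_to_p = dt_p[st]
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_p_to_t, d_t_to_p]), 95))
    if mode == "max_directed":
        return float(max(np.percentile(d_p_to_t, 95), np.percentile(d_t_to_p, 95)))
    raise ValueError(f"unknown hd95 mode: {mode}")


def region_report(pred_labels: np.ndarray, true_labels: np.ndarray, spacing=None,
                  hd95_mode: str = "pooled") -> dict[str, dict[str, float]]:
    """Per-region DSC and HD95 for the nested BraTS regions."""
    from .brats_io import derive_regions

    pr = derive_regions(pred_labels)
    tr = derive_regions(true_labels)
    report = {}
    for (name, pm), (_, tm) in zip(pr, tr):
        report[name] = {
            "dsc": dsc(pm, tm),
            "hd95": hd95(pm, tm, spacing=spacing, mode=hd95_mode),
        }
    return report
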