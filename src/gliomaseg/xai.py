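"""Post-hoc Grad-CAM saliency for the segmentation network.

For a scalar class score y^c, the Grad-CAM map at an internal layer with
activations A^l is

    alpha_l^c = (1/N) sum_{x,y} dy^c / dA^l_{x,y}      (spatial mean gradient)
    L^c       = ReLU( sum_l alpha_l^c A^l )            (channelwise weighting)

upsampled bilinearly to the input grid and min-max normalized.  For dense
segmentation output the class score y^c is not uniquely defined; the default
aggregates the class-c pre-softmax score over the pixels predicted as class
c (falling back to all pixels when the class is absent), and both an
all-pixel and an ROI-masked variant are available.

Explanation generation is strictly post hoc: it never changes model weights.

The modality-ablation experiment zeroes input channels at inference time
(zero is the background value after z-scoring) in both keep-only and
leave-one-out directions, and records how each region's dice responds —
on phantoms with planted modality-specific contrast this has a known answer
(edema is only visible on FLAIR/T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .brats_io import MODALITIES, LabelVolume, MultimodalVolume, derive_regions, indices_to_labels
from .net import HybridSegNet, LAYER_TAGS
from .nn import Tensor
from .objective import region_report
from .preprocess import extract_axial_slices, preprocess_case

CLASS_NAMES = ("background", "NCR", "ED", "ET")  # class indices 0..3 <-> labels 0,1,2,4


@dataclass
class ClassScoreSpec:
    """Defines the scalar y^c whose gradient drives Grad-CAM."""

    target_class: int
    aggregation: str = "predicted-pixels"  # all-pixels | predicted-pixels | roi-mask
    score_source: str = "logit"            # logit | softmax
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.target_class not in (0, 1, 2, 3):
            raise ValueError("target_class must be a class index in 0..3")
        if self.aggregation not in ("all-pixels", "predicted-pixels", "roi-mask"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.score_source not in ("logit", "softmax"):
            raise ValueError(f"unknown score source {self.score_source!r}")
        if self.aggregation == "roi-mask" and self.roi_mask is None:
            raise ValueError("roi-mask aggregation requires roi_mask")


@dataclass
class SaliencyMap:
    heatmap: np.ndarray          # (H, W), in [0, 1]
    target_class: int
    layer: str
    aggregation: str
    all_zero: bool = False


def _normalize(heat: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize to [0, 1]; an all-zero map is kept all-zero and flagged."""
    hmax, hmin = float(heat.max()), float(heat.min())
    if hmax <= 0.0:
        return np.zeros_like(heat), True
    out = (heat - hmin) / (hmax - hmin) if hmax > hmin else np.ones_like(heat)
    return out, False


def _upsample(heat: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if heat.shape == tuple(size):
        return heat
    factors = (size[0] / heat.shape[0], size[1] / heat.shape[1])
    return ndimage.zoom(heat, factors, order=1)[: size[0], : size[1]]


def _class_score(logits: Tensor, spec: ClassScoreSpec) -> Tensor:
    """Build the scalar y^c from the (1, C, H, W) output tensor."""
    score = logits.softmax(axis=1) if spec.score_source == "softmax" else logits
    cls_map = score[:, spec.target_class, :, :]  # (1, H, W)
    if spec.aggregation == "all-pixels":
        return cls_map.sum()
    if spec.aggregation == "roi-mask":
        return (cls_map * Tensor(np.asarray(spec.roi_mask, dtype=np.float32)[None])).sum()
    pred = logits.data.argmax(axis=1) == spec.target_class  # predicted-pixels
    if not pred.any():
        return cls_map.sum()
    return (cls_map * Tensor(pred.astype(np.float32))).sum()


def _grad_cam_all_layers(model, image: np.ndarray, spec: ClassScoreSpec,
                         layers: list[str], normalize: bool = True) -> dict[str, SaliencyMap]:
    """One forward/backward pass; maps for every requested layer tag.

    ``model`` needs the tagged-forward interface: ``forward_features(x) ->
    (logits, {tag: activation})`` plus ``cfg.in_channels``, ``eval`` and
    ``zero_grad`` — satisfied by :class:`HybridSegNet` and by toy networks
    in tests.
    """
    model.eval()
    img = np.asarray(image)
    if img.dtype.kind != "f":
        img = img.astype(np.float32)
    if img.ndim != 3 or img.shape[-1] != model.cfg.in_channels:
        raise ValueError(f"image must be (H, W, {model.cfg.in_channels})")
    x = Tensor(img.transpose(2, 0, 1)[None])
    logits, acts = model.forward_features(x)
    unknown = [t for t in layers if t not in acts]
    if unknown:
        raise ValueError(f"unknown layer tag(s) {unknown}; available: {list(acts)}")
    y = _class_score(logits, spec)
    model.zero_grad()
    y.backward()
    size = img.shape[:2]
    maps = {}
    for tag in layers:
        a = acts[tag]
        if a.grad is None:
            heat = np.zeros(a.shape[2:], dtype=np.float32)
        else:
            alpha = a.grad.mean(axis=(2, 3))              # (1, C) spatial-mean gradients
            heat = np.maximum((alpha[0][:, None, None] * a.data[0]).sum(axis=0), 0.0)
        heat = _upsample(heat, size)
        if normalize:
            heat, all_zero = _normalize(heat)
        else:
            all_zero = bool(heat.max() <= 0.0)
        maps[tag] = SaliencyMap(heatmap=heat, target_class=spec.target_class,
                                layer=tag, aggregation=spec.aggregation, all_zero=all_zero)
    model.zero_grad()
    return maps


def grad_cam(model, image: np.ndarray, layer: str, spec: ClassScoreSpec,
             normalize: bool = True) -> SaliencyMap:
    """Grad-CAM saliency for one internal layer and one target class."""
    return _grad_cam_all_layers(model, image, spec, [layer], normalize=normalize)[layer]


def layer_sweep(model, image: np.ndarray, spec: ClassScoreSpec,
                layers: list[str] | None = None) -> dict[str, SaliencyMap]:
    """Saliency maps across the network depth (EB1..EB4, BOT, DB1..DB4, OUT)."""
    return _grad_cam_all_layers(model, image, spec, list(layers or LAYER_TAGS))


# -------------------------------------------------------------- ablation
def _predict_with_channel_mask(model: HybridSegNet, pvol, keep: np.ndarray) -> np.ndarray:
    from .train import _predict_cropped

    masked = {m: (pvol.channels[m] if keep[i] else np.zeros_like(pvol.channels[m]))
              for i, m in enumerate(MODALITIES)}
    return _predict_cropped(model, pvol.replace_channels(masked))


def modality_ablation(
    model: HybridSegNet,
    vol: MultimodalVolume,
    labels: LabelVolume,
    crop_size: tuple[int, int] = (192, 192),
    include_saliency: bool = False,
) -> tuple[list[dict], dict[str, dict[str, SaliencyMap]]]:
    """Inference-time channel ablation, both keep-only and leave-one-out.

    Returns one report row per (mode, modality) with per-region DSC against
    the ground truth, plus (optionally) output-layer Grad-CAM maps per class
    for each keep-only condition.
    """
    pvol, plab, _ = preprocess_case(vol, labels, crop_size=crop_size)
    rows: list[dict] = []
    saliency: dict[str, dict[str, SaliencyMap]] = {}
    for mode in ("keep_only", "leave_one_out"):
        for i, m in enumerate(MODALITIES):
            keep = np.zeros(len(MODALITIES), dtype=bool)
            keep[i] = True
            if mode == "leave_one_out":
                keep = ~keep
            pred = _predict_with_channel_mask(model, pvol, keep)
            rep = region_report(pred, plab.labels)
            row = {"mode": mode, "modality": m}
            for region, vals in rep.items():
                row[f"{region}_dsc"] = vals["dsc"]
            rows.append(row)
    if include_saliency:
        mid = plab.labels.shape[2] // 2
        stack = pvol.stacked()[:, :, mid, :]
        for i, m in enumerate(MODALITIES):
            keep = np.zeros(len(MODALITIES), dtype=bool)
            keep[i] = True
            img = stack * keep[None, None, :]
            saliency[m] = {
                CLASS_NAMES[c]: grad_cam(model, img, "OUT", ClassScoreSpec(target_class=c))
                for c in range(1, 4)
            }
    return rows, saliency
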