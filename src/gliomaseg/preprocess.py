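"""Case preprocessing: brain-FOV zeroing, z-score, 192x192 center crop, slicing.

The pipeline mirrors standard multimodal-MRI preparation for 2D axial
segmentation: non-brain voxels are forced to exactly zero, each channel is
z-scored over brain voxels of the whole 3D volume (population standard
deviation), the in-plane field of view is center-cropped (or zero-padded) to
a fixed size, and axial slices are extracted along the third axis.  Every
step records enough geometry in a :class:`PreprocRecord` to map slice-level
predictions back onto the original volume grid exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .brats_io import MODALITIES, LabelVolume, MultimodalVolume

DEFAULT_CROP = (192, 192)
#: connected components smaller than this fraction of the largest one are
#: treated as non-brain speckle when building the brain mask
MIN_COMPONENT_FRACTION = 0.01


@dataclass
class ChannelStats:
    mean: float
    std: float
    zero_std_fallback: bool = False


@dataclass
class PreprocRecord:
    """Geometry and normalization bookkeeping needed to invert preprocessing."""

    original_shape: tuple[int, int, int]
    crop_offsets: tuple[int, int] = (0, 0)
    crop_size: tuple[int, int] = DEFAULT_CROP
    normalization: dict[str, ChannelStats] = field(default_factory=dict)

    def to_json(self, path: Path | str):
        payload = {
            "original_shape": list(self.original_shape),
            "crop_offsets": list(self.crop_offsets),
            "crop_size": list(self.crop_size),
            "normalization": {
                m: {"mean": s.mean, "std": s.std, "zero_std_fallback": s.zero_std_fallback}
                for m, s in self.normalization.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "PreprocRecord":
        d = json.loads(Path(path).read_text())
        rec = cls(tuple(d["original_shape"]), tuple(d["crop_offsets"]), tuple(d["crop_size"]))
        rec.normalization = {
            m: ChannelStats(s["mean"], s["std"], s["zero_std_fallback"])
            for m, s in d["normalization"].items()
        }
        return rec


@dataclass
class SlicePair:
    """One axial 2D multimodal image (H, W, 4) with its label map and index."""

    image: np.ndarray
    label: np.ndarray | None
    index: int


# ----------------------------------------------------------------- brain FOV
def brain_mask(vol: MultimodalVolume) -> np.ndarray:
    """Union of nonzero voxels across channels, small components removed.

    Components smaller than ``MIN_COMPONENT_FRACTION`` of the largest
    connected component are discarded (speckle outside the head).
    """
    union = np.zeros(vol.shape, dtype=bool)
    for m in MODALITIES:
        union |= vol.channels[m] != 0
    if not union.any():
        raise ValueError("volume is entirely zero; no brain voxels found")
    lab, n = ndimage.label(union)
    if n == 1:
        return union
    sizes = ndimage.sum_labels(union, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= MIN_COMPONENT_FRACTION * sizes.max()) + 1
    return np.isin(lab, keep)


def zero_nonbrain(vol: MultimodalVolume) -> MultimodalVolume:
    """Force voxels outside the brain mask to exactly zero in all channels.

    Idempotent: skull-stripped inputs with a clean zero background pass
    through unchanged.
    """
    mask = brain_mask(vol)
    out = {m: np.where(mask, vol.channels[m], 0.0).astype(np.float32) for m in MODALITIES}
    return vol.replace_channels(out)


# -------------------------------------------------------------------- z-score
def zscore(vol: MultimodalVolume, mask: np.ndarray | None = None) -> tuple[MultimodalVolume, PreprocRecord]:
    """Per-channel z-score over brain voxels; background stays exactly zero.

    Uses the population standard deviation.  A constant channel (std 0)
    falls back to std 1 and is flagged in the record.
    """
    if mask is None:
        mask = brain_mask(vol)
    if not mask.any():
        raise ValueError("empty brain mask")
    rec = PreprocRecord(original_shape=tuple(vol.shape))
    out = {}
    for m in MODALITIES:
        vals = vol.channels[m][mask]
        mu = float(vals.mean())
        sd = float(vals.std())
        fallback = sd == 0.0
        if fallback:
            sd = 1.0
        rec.normalization[m] = ChannelStats(mu, sd, fallback)
        ch = np.zeros(vol.shape, dtype=np.float32)
        ch[mask] = (vol.channels[m][mask] - mu) / sd
        out[m] = ch
    return vol.replace_channels(out), rec


# ----------------------------------------------------------------- crop / pad
def _axis_window(dim: int, size: int) -> tuple[int, slice, slice]:
    """Offset plus (source, destination) slices for one in-plane axis.

    A negative offset means the input was zero-padded by ``-offset`` voxels
    before the window.
    """
    off = (dim - size) // 2
    if off >= 0:
        return off, slice(off, off + size), slice(0, size)
    pad_before = -off
    return off, slice(0, dim), slice(pad_before, pad_before + dim)


def center_crop(
    vol: MultimodalVolume,
    labels: LabelVolume | None = None,
    size: tuple[int, int] = DEFAULT_CROP,
    record: PreprocRecord | None = None,
) -> tuple[MultimodalVolume, LabelVolume | None, PreprocRecord]:
    """Center-crop (or zero-pad) the in-plane axes to ``size``; depth untouched."""
    h, w, d = vol.shape
    off0, src0, dst0 = _axis_window(h, size[0])
    off1, src1, dst1 = _axis_window(w, size[1])
    rec = record or PreprocRecord(original_shape=(h, w, d))
    rec.crop_offsets = (off0, off1)
    rec.crop_size = tuple(size)

    def apply(arr: np.ndarray, fill=0) -> np.ndarray:
        out = np.full((size[0], size[1], d), fill, dtype=arr.dtype)
        out[dst0, dst1, :] = arr[src0, src1, :]
        return out

    cvol = vol.replace_channels({m: apply(vol.channels[m]) for m in MODALITIES})
    clab = None
    if labels is not None:
        clab = LabelVolume(apply(labels.labels), labels.affine, labels.spacing)
    return cvol, clab, rec


def invert_crop(cropped: np.ndarray, record: PreprocRecord, fill=0) -> np.ndarray:
    """Place a cropped (H, W, D[, C]) array back on the original in-plane grid."""
    h, w, d = record.original_shape
    _, src0, dst0 = _axis_window(h, record.crop_size[0])
    _, src1, dst1 = _axis_window(w, record.crop_size[1])
    out_shape = (h, w) + cropped.shape[2:]
    out = np.full(out_shape, fill, dtype=cropped.dtype)
    out[src0, src1, ...] = cropped[dst0, dst1, ...]
    return out


# -------------------------------------------------------------------- slicing
def extract_axial_slices(vol: MultimodalVolume, labels: LabelVolume | None = None) -> list[SlicePair]:
    """One SlicePair per axial index; channel order fixed (T1, T1Gd, T2, FLAIR)."""
    stack = vol.stacked()  # (H, W, D, 4)
    d = stack.shape[2]
    lab = labels.labels if labels is not None else None
    return [
        SlicePair(
            image=np.ascontiguousarray(stack[:, :, k, :]),
            label=(np.ascontiguousarray(lab[:, :, k]) if lab is not None else None),
            index=k,
        )
        for k in range(d)
    ]


def filter_slices(slices: list[SlicePair], min_brain_fraction: float = 0.01) -> list[SlicePair]:
    """Keep slices whose nonzero-pixel fraction reaches ``min_brain_fraction``."""
    kept = []
    for sp in slices:
        frac = float((np.abs(sp.image).sum(axis=-1) != 0).mean())
        if frac >= min_brain_fraction:
            kept.append(sp)
    return kept


def reassemble_slices(slices: list[SlicePair], attr: str = "label") -> np.ndarray:
    """Stack per-slice arrays back into a volume along the third axis."""
    ordered = sorted(slices, key=lambda s: s.index)
    if [s.index for s in ordered] != list(range(len(ordered))):
        raise ValueError("slice indices are not contiguous from 0")
    arrs = [getattr(s, attr) for s in ordered]
    return np.stack(arrs, axis=2)


def preprocess_case(
    vol: MultimodalVolume,
    labels: LabelVolume | None = None,
    crop_size: tuple[int, int] = DEFAULT_CROP,
) -> tuple[MultimodalVolume, LabelVolume | None, PreprocRecord]:
    """Full pipeline: zero non-brain, z-score, center crop."""
    vol = zero_nonbrain(vol)
    vol, rec = zscore(vol)
    vol, labels, rec = center_crop(vol, labels, size=crop_size, record=rec)
    return vol, labels, rec
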