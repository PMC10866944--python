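"""BraTS-layout case I/O: NIfTI reading/writing, label codec, evaluation regions.

A case is a directory with four skull-stripped, co-registered modality volumes
(T1, T1Gd, T2, FLAIR) and optionally an integer segmentation with values
{0, 1, 2, 4}: 1 = necrotic/non-enhancing core, 2 = peritumoral edema,
4 = enhancing tumor.  Evaluation regions are the nested BraTS composites
ET (4) ⊆ TC (1∪4) ⊆ WT (1∪2∪4).

All volumes are reoriented to a single canonical orientation (RAS) at load
time; axial slices are taken along the third array axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("T1", "T1Gd", "T2", "FLAIR")
VALID_LABELS = (0, 1, 2, 4)

#: filename-stem suffixes per modality; BraTS naming drifts across years,
#: so T1Gd accepts both "_t1ce" and "_t1gd".  Matched case-insensitively.
DEFAULT_SUFFIXES: dict[str, tuple[str, ...]] = {
    "T1": ("_t1",),
    "T1Gd": ("_t1ce", "_t1gd"),
    "T2": ("_t2",),
    "FLAIR": ("_flair",),
    "seg": ("_seg",),
}

_LABEL_TO_INDEX = {0: 0, 1: 1, 2: 2, 4: 3}
_INDEX_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.uint8)


class CaseError(ValueError):
    """Fatal problem with an on-disk case (missing file, bad geometry, bad labels)."""


@dataclass
class MultimodalVolume:
    """Four aligned 3D scalar channels plus shared geometry."""

    channels: dict[str, np.ndarray]
    affine: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.channels]
        if missing:
            raise CaseError(f"missing modality channel(s): {missing}")
        shapes = {m: self.channels[m].shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise CaseError(f"channel shapes disagree: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[MODALITIES[0]].shape

    def stacked(self) -> np.ndarray:
        """Channel-last stack (H, W, D, 4) in the fixed modality order."""
        return np.stack([self.channels[m] for m in MODALITIES], axis=-1)

    def replace_channels(self, arrays: dict[str, np.ndarray]) -> "MultimodalVolume":
        return MultimodalVolume(dict(arrays), self.affine, self.spacing, self.orientation)


@dataclass
class LabelVolume:
    """Integer segmentation sharing geometry with its MultimodalVolume."""

    labels: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise CaseError(f"label volume contains invalid value(s): {sorted(int(v) for v in bad)}")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class RegionMasks:
    """Nested evaluation masks ET ⊆ TC ⊆ WT."""

    ET: np.ndarray
    TC: np.ndarray
    WT: np.ndarray

    def __iter__(self):
        yield from (("ET", self.ET), ("TC", self.TC), ("WT", self.WT))


# --------------------------------------------------------------------- codec
def labels_to_class_indices(labels: np.ndarray) -> np.ndarray:
    """Map BraTS labels {0,1,2,4} to contiguous class indices {0,1,2,3}."""
    bad = np.setdiff1d(np.unique(labels), VALID_LABELS)
    if bad.size:
        raise CaseError(f"cannot index invalid label value(s): {sorted(int(v) for v in bad)}")
    out = np.asarray(labels).copy()
    out[out == 4] = 3
    return out.astype(np.int64)


def indices_to_labels(indices: np.ndarray) -> np.ndarray:
    """Inverse of :func:`labels_to_class_indices`."""
    idx = np.asarray(indices)
    bad = np.setdiff1d(np.unique(idx), [0, 1, 2, 3])
    if bad.size:
        raise CaseError(f"invalid class index value(s): {sorted(int(v) for v in bad)}")
    return _INDEX_TO_LABEL[idx]


def derive_regions(labels: np.ndarray | LabelVolume) -> RegionMasks:
    """Evaluation regions: ET = {4}, TC = {1,4}, WT = {1,2,4}."""
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    et = arr == 4
    tc = et | (arr == 1)
    wt = tc | (arr == 2)
    return RegionMasks(ET=et, TC=tc, WT=wt)


# ----------------------------------------------------------------------- I/O
def _stem(path: Path) -> str:
    name = path.name.lower()
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return name


def resolve_case(case_dir: Path | str, suffixes: dict[str, tuple[str, ...]] | None = None) -> dict[str, Path | None]:
    """Discover modality/segmentation files in a case directory by suffix."""
    case_dir = Path(case_dir)
    suffixes = suffixes or DEFAULT_SUFFIXES
    files = sorted(p for p in case_dir.iterdir() if p.name.lower().endswith((".nii", ".nii.gz")))
    resolved: dict[str, Path | None] = {}
    for key, sufs in suffixes.items():
        hits = [p for p in files if any(_stem(p).endswith(s.lower()) for s in sufs)]
        if len(hits) > 1:
            raise CaseError(f"ambiguous files for {key} in {case_dir}: {[p.name for p in hits]}")
        resolved[key] = hits[0] if hits else None
    return resolved


def write_manifest(case_dir: Path | str, out_path: Path | str | None = None) -> Path:
    """Write a JSON manifest of resolved per-modality file paths."""
    case_dir = Path(case_dir)
    resolved = resolve_case(case_dir)
    out_path = Path(out_path) if out_path else case_dir / "manifest.json"
    out_path.write_text(json.dumps({k: (str(v) if v else None) for k, v in resolved.items()}, indent=2))
    return out_path


def _load_canonical(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    return data, img.affine, tuple(float(z) for z in img.header.get_zooms()[:3])


def load_case(case_dir: Path | str, suffixes: dict[str, tuple[str, ...]] | None = None) -> tuple[MultimodalVolume, LabelVolume | None]:
    """Load one BraTS-layout case, reoriented to the canonical (RAS) orientation.

    Raises :class:`CaseError` if a modality is missing, geometries disagree,
    or the segmentation contains a value outside {0, 1, 2, 4}.
    """
    resolved = resolve_case(case_dir, suffixes)
    missing = [m for m in MODALITIES if resolved.get(m) is None]
    if missing:
        raise CaseError(f"case {case_dir}: missing modality file(s) for {missing}")
    channels, affine, spacing = {}, None, None
    for m in MODALITIES:
        data, aff, zooms = _load_canonical(resolved[m])
        channels[m] = np.asarray(data, dtype=np.float32)
        if affine is None:
            affine, spacing = aff, zooms
        elif not np.allclose(aff, affine, atol=1e-4):
            raise CaseError(f"case {case_dir}: affine of {m} disagrees with {MODALITIES[0]}")
    vol = MultimodalVolume(channels, affine, spacing)
    label_vol = None
    if resolved.get("seg") is not None:
        seg, seg_aff, _ = _load_canonical(resolved["seg"])
        seg = np.rint(np.asarray(seg)).astype(np.int16)
        if seg.shape != vol.shape:
            raise CaseError(f"case {case_dir}: label shape {seg.shape} != image shape {vol.shape}")
        if not np.allclose(seg_aff, affine, atol=1e-4):
            raise CaseError(f"case {case_dir}: label affine disagrees with image affine")
        label_vol = LabelVolume(seg, affine, spacing)
    return vol, label_vol


def save_volume(data: np.ndarray, affine: np.ndarray, out_path: Path | str, dtype=np.float32) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(out_path))
    return out_path


def save_prediction(labels: np.ndarray | LabelVolume, reference: MultimodalVolume | LabelVolume, out_path: Path | str) -> Path:
    """Write a predicted segmentation as uint8 NIfTI on the reference geometry."""
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
    if bad.size:
        raise CaseError(f"prediction contains invalid label value(s): {sorted(int(v) for v in bad)}")
    if tuple(arr.shape) != tuple(reference.shape):
        raise CaseError(f"prediction shape {arr.shape} != reference shape {reference.shape}")
    return save_volume(arr.astype(np.uint8), reference.affine, out_path, dtype=np.uint8)
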