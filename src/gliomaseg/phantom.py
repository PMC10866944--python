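"""Synthetic multimodal glioma phantoms with known ground truth.

Each phantom is an ellipsoidal "brain" inside a zero background, carrying a
nested spherical tumor: a necrotic core (label 1) wrapped by an enhancing rim
(label 4) wrapped by an edema shell (label 2).  Channel intensities follow
the radiological contrast pattern of high-grade glioma: edema is bright on
FLAIR/T2 but indistinguishable from white matter on T1/T1Gd, the enhancing
rim is the brightest tissue on T1Gd, and the necrotic core is dark on T1Gd.
That planted structure gives every downstream stage — segmentation, fusion,
and per-modality attribution — a known answer.

Default geometry is 96x96x32 voxels: large enough to exercise padding and
cropping paths, small enough for desk-scale training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .brats_io import MODALITIES, LabelVolume, MultimodalVolume, save_volume

TISSUES = ("background", "white_matter", "gray_matter", "edema", "necrotic_core", "enhancing")

#: mean intensity per modality and tissue (arbitrary units).  Edema equals
#: white matter on T1 and T1Gd by construction, so only T2/FLAIR carry the
#: edema-vs-white-matter contrast.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "T1": {"background": 0.0, "white_matter": 1.0, "gray_matter": 0.8, "edema": 1.0, "necrotic_core": 0.5, "enhancing": 0.9},
    "T1Gd": {"background": 0.0, "white_matter": 1.0, "gray_matter": 0.8, "edema": 1.0, "necrotic_core": 0.4, "enhancing": 1.8},
    "T2": {"background": 0.0, "white_matter": 0.7, "gray_matter": 0.9, "edema": 1.3, "necrotic_core": 1.1, "enhancing": 0.9},
    "FLAIR": {"background": 0.0, "white_matter": 0.6, "gray_matter": 0.8, "edema": 1.5, "necrotic_core": 1.0, "enhancing": 0.9},
}


@dataclass
class PhantomSpec:
    image_shape: tuple[int, int, int] = (96, 96, 32)
    brain_axes: tuple[float, float, float] = (40.0, 40.0, 14.0)
    tumor_center: tuple[float, float, float] | None = None  # None -> brain center
    wt_radius: float = 10.0
    tc_radius: float = 6.5
    core_radius: float = 3.5
    gray_matter_shell: float = 0.8  # normalized ellipse radius beyond which tissue is gray matter
    contrast_table: dict[str, dict[str, float]] = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_std: float = 0.05
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not (self.core_radius < self.tc_radius < self.wt_radius):
            raise ValueError("radii must nest: core < TC < WT")
        for m in MODALITIES:
            tbl = self.contrast_table[m]
            missing = [t for t in TISSUES if t not in tbl]
            if missing:
                raise ValueError(f"contrast table for {m} missing tissues {missing}")
            if tbl["background"] != 0.0:
                raise ValueError("background contrast must be 0")

    def to_json(self, path: Path | str):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for key in ("image_shape", "brain_axes", "spacing"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("tumor_center") is not None:
            d["tumor_center"] = tuple(d["tumor_center"])
        return cls(**d)


def _tissue_map(spec: PhantomSpec) -> np.ndarray:
    """Integer tissue id per voxel, indexing into :data:`TISSUES`."""
    shape = spec.image_shape
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    # normalized ellipse radius
    r_ell = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, spec.brain_axes)))
    brain = r_ell <= 1.0
    tc = spec.tumor_center if spec.tumor_center is not None else tuple(center)
    r_tum = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, tc)))
    if (np.sqrt(sum(((t - c) / a) ** 2 for t, c, a in zip(tc, center, spec.brain_axes)))
            + spec.wt_radius / min(spec.brain_axes)) > 1.0 + 1e-9:
        raise ValueError("tumor (center + WT radius) exceeds the brain ellipse")
    tissue = np.zeros(shape, dtype=np.int8)  # background
    tissue[brain & (r_ell <= spec.gray_matter_shell)] = TISSUES.index("white_matter")
    tissue[brain & (r_ell > spec.gray_matter_shell)] = TISSUES.index("gray_matter")
    tissue[brain & (r_tum <= spec.wt_radius)] = TISSUES.index("edema")
    tissue[brain & (r_tum <= spec.tc_radius)] = TISSUES.index("enhancing")
    tissue[brain & (r_tum <= spec.core_radius)] = TISSUES.index("necrotic_core")
    return tissue


_TISSUE_TO_LABEL = {"background": 0, "white_matter": 0, "gray_matter": 0,
                    "necrotic_core": 1, "edema": 2, "enhancing": 4}


def generate_case(spec: PhantomSpec) -> tuple[MultimodalVolume, LabelVolume]:
    """Deterministically render one phantom case from its spec."""
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_map(spec)
    brain = tissue != 0
    labels = np.zeros(spec.image_shape, dtype=np.int16)
    for name, lab in _TISSUE_TO_LABEL.items():
        if lab:
            labels[tissue == TISSUES.index(name)] = lab
    affine = np.diag(list(spec.spacing) + [1.0])
    channels = {}
    for m in MODALITIES:
        lut = np.array([spec.contrast_table[m][t] for t in TISSUES], dtype=np.float32)
        ch = lut[tissue]
        if spec.noise_std > 0:
            ch = ch + rng.normal(0.0, spec.noise_std, size=ch.shape).astype(np.float32)
        ch[~brain] = 0.0  # non-brain stays exactly zero
        channels[m] = ch.astype(np.float32)
    vol = MultimodalVolume(channels, affine, spec.spacing)
    return vol, LabelVolume(labels, affine, spec.spacing)


def analytic_region_counts(spec: PhantomSpec) -> dict[str, int]:
    """Exact voxel counts of ET/TC/WT by exhaustive scan of the shell conditions."""
    tissue = _tissue_map(spec)
    et = int((tissue == TISSUES.index("enhancing")).sum())
    core = int((tissue == TISSUES.index("necrotic_core")).sum())
    ed = int((tissue == TISSUES.index("edema")).sum())
    return {"ET": et, "TC": et + core, "WT": et + core + ed}


def generate_cohort(
    n: int,
    out_dir: Path | str,
    base_spec: PhantomSpec | None = None,
    jitter: float = 3.0,
    seed: int = 0,
) -> list[Path]:
    """Write ``n`` phantom cases in BraTS layout under ``out_dir``.

    Tumor center and radii are jittered deterministically from ``seed``;
    ``jitter`` is the maximum absolute displacement/radius change in voxels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n):
        center = [(s - 1) / 2.0 for s in base.image_shape]
        dc = rng.uniform(-jitter, jitter, size=3) if jitter > 0 else np.zeros(3)
        dr = rng.uniform(-jitter / 2.0, jitter / 2.0) if jitter > 0 else 0.0
        spec = PhantomSpec(
            image_shape=base.image_shape,
            brain_axes=base.brain_axes,
            tumor_center=tuple(float(c + d) for c, d in zip(center, dc * [1, 1, 0.3])),
            wt_radius=base.wt_radius + float(dr),
            tc_radius=base.tc_radius + float(dr) * 0.5,
            core_radius=base.core_radius + float(dr) * 0.25,
            gray_matter_shell=base.gray_matter_shell,
            contrast_table={m: dict(v) for m, v in base.contrast_table.items()},
            noise_std=base.noise_std,
            spacing=base.spacing,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, lab = generate_case(spec)
        case_dir = out_dir / f"phantom_{i:03d}"
        case_dir.mkdir(parents=True, exist_ok=True)
        stem = case_dir.name
        for m, suffix in (("T1", "_t1"), ("T1Gd", "_t1ce"), ("T2", "_t2"), ("FLAIR", "_flair")):
            save_volume(vol.channels[m], vol.affine, case_dir / f"{stem}{suffix}.nii.gz")
        save_volume(lab.labels.astype(np.uint8), lab.affine, case_dir / f"{stem}_seg.nii.gz", dtype=np.uint8)
        spec.to_json(case_dir / f"{stem}_phantom_spec.json")
        paths.append(case_dir)
    return paths
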