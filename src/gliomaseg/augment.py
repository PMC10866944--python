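"""On-the-fly joint image/label augmentation for 2D multimodal slices.

Spatial transforms — horizontal/vertical shift, horizontal/vertical flip,
rotation up to 20 degrees (random sign), zoom within ±20% — are applied
identically to the image (bilinear) and the label map (nearest neighbor).
Intensity transforms — multiplicative brightness within ±20% and additive
Gaussian noise with standard deviation 0.01 in normalized units — touch the
image channels only.  Out-of-frame regions are filled with the background
value 0 for both image and label.

Parameter sampling is separated from application so tests can force exact
transform parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import SlicePair


@dataclass
class AugmentConfig:
    shift_fraction: float = 0.10   # max |shift| per in-plane axis, fraction of size
    flip_prob: float = 0.5         # per axis
    rotation_max_deg: float = 20.0
    zoom_max_fraction: float = 0.20
    brightness_max_fraction: float = 0.20
    noise_std: float = 0.01
    enabled: bool = True

    def __post_init__(self):
        for name in ("shift_fraction", "flip_prob", "zoom_max_fraction", "brightness_max_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rotation_max_deg < 0 or self.noise_std < 0:
            raise ValueError("rotation_max_deg and noise_std must be >= 0")


@dataclass
class AugmentParams:
    """One concrete draw of transform parameters (reproducible, loggable)."""

    shift: tuple[float, float] = (0.0, 0.0)   # voxels, per in-plane axis
    flip: tuple[bool, bool] = (False, False)
    angle_deg: float = 0.0
    zoom: float = 1.0
    brightness: float = 1.0
    noise_seed: int | None = None
    noise_std: float = 0.0

    def as_dict(self) -> dict:
        return {
            "shift": list(self.shift), "flip": list(self.flip), "angle_deg": self.angle_deg,
            "zoom": self.zoom, "brightness": self.brightness,
            "noise_seed": self.noise_seed, "noise_std": self.noise_std,
        }


def sample_params(cfg: AugmentConfig, rng: np.random.Generator, size: tuple[int, int]) -> AugmentParams:
    """Draw transform parameters: shifts ~ U(-s, s) voxels, flips ~ Bernoulli,
    |angle| ~ U(0, max) with random sign, zoom ~ U(1-z, 1+z),
    brightness ~ U(1-b, 1+b)."""
    if not cfg.enabled:
        return AugmentParams()
    smax = (cfg.shift_fraction * size[0], cfg.shift_fraction * size[1])
    shift = (float(rng.uniform(-smax[0], smax[0])), float(rng.uniform(-smax[1], smax[1])))
    flip = (bool(rng.random() < cfg.flip_prob), bool(rng.random() < cfg.flip_prob))
    angle = float(rng.uniform(0.0, cfg.rotation_max_deg)) * float(rng.choice([-1.0, 1.0]))
    zoom = float(rng.uniform(1.0 - cfg.zoom_max_fraction, 1.0 + cfg.zoom_max_fraction))
    brightness = float(rng.uniform(1.0 - cfg.brightness_max_fraction, 1.0 + cfg.brightness_max_fraction))
    return AugmentParams(shift=shift, flip=flip, angle_deg=angle, zoom=zoom,
                         brightness=brightness, noise_seed=int(rng.integers(0, 2**31 - 1)),
                         noise_std=cfg.noise_std)


def _warp(arr: np.ndarray, params: AugmentParams, order: int) -> np.ndarray:
    """Apply rotation+zoom+shift about the center; order 1 for image, 0 for labels."""
    theta = np.deg2rad(params.angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    inv = np.array([[c, s], [-s, c]]) / params.zoom  # inverse of rot(theta)*zoom
    center = (np.asarray(arr.shape[:2]) - 1) / 2.0
    # out(x) = in( inv @ (x - center - shift) + center )
    offset = inv @ (-center - np.asarray(params.shift)) + center
    if arr.ndim == 3:
        out = np.stack(
            [ndimage.affine_transform(arr[..., k], inv, offset=offset, order=order, cval=0.0, mode="constant")
             for k in range(arr.shape[-1])], axis=-1)
        return out
    return ndimage.affine_transform(arr, inv, offset=offset, order=order, cval=0.0, mode="constant")


def apply_params(pair: SlicePair, params: AugmentParams) -> SlicePair:
    """Apply one concrete parameter draw to a slice pair."""
    img = pair.image.astype(np.float32)
    lab = pair.label
    for ax, do_flip in enumerate(params.flip):
        if do_flip:
            img = np.flip(img, axis=ax)
            if lab is not None:
                lab = np.flip(lab, axis=ax)
    identity_warp = (params.angle_deg == 0.0 and params.zoom == 1.0 and params.shift == (0.0, 0.0))
    if not identity_warp:
        img = _warp(img, params, order=1)
        if lab is not None:
            lab = _warp(lab.astype(np.int16), params, order=0)
    img = img * params.brightness
    if params.noise_std > 0 and params.noise_seed is not None:
        nrng = np.random.default_rng(params.noise_seed)
        img = img + nrng.normal(0.0, params.noise_std, size=img.shape).astype(np.float32)
    return SlicePair(image=np.ascontiguousarray(img, dtype=np.float32),
                     label=(np.ascontiguousarray(lab) if lab is not None else None),
                     index=pair.index)


def augment_pair(pair: SlicePair, cfg: AugmentConfig, rng: np.random.Generator) -> tuple[SlicePair, AugmentParams]:
    """Sample parameters and apply them; returns the pair and the logged draw."""
    params = sample_params(cfg, rng, pair.image.shape[:2])
    return apply_params(pair, params), params
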