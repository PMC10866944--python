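"""Schema-validated run configuration (YAML/JSON, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataBlock(_Strict):
    data_dir: str = "cases"
    n_cases: int = Field(6, ge=1)
    jitter: float = Field(3.0, ge=0)
    noise_std: float = Field(0.05, ge=0)
    image_shape: tuple[int, int, int] = (96, 96, 32)


class PreprocessBlock(_Strict):
    crop_size: tuple[int, int] = (192, 192)
    min_brain_fraction: float = Field(0.01, ge=0, le=1)


class TransformerBlockCfg(_Strict):
    num_blocks: int = Field(4, ge=1)
    num_heads: int = Field(8, ge=1)
    embed_dim: int = Field(256, ge=1)
    mlp_dim: int = Field(1024, ge=1)
    patch_size: int = Field(1, ge=1)


class ModelBlock(_Strict):
    in_channels: int = 4
    num_classes: int = 4
    base_filters: int = Field(32, ge=1)
    encoder_levels: int = 4
    input_size: tuple[int, int] = (192, 192)
    transformer: TransformerBlockCfg = Field(default_factory=TransformerBlockCfg)
    head_bias_prior: tuple[float, float, float, float] | None = None


class AugmentBlock(_Strict):
    enabled: bool = True
    shift_fraction: float = Field(0.10, ge=0, le=1)
    flip_prob: float = Field(0.5, ge=0, le=1)
    rotation_max_deg: float = Field(20.0, ge=0)
    zoom_max_fraction: float = Field(0.20, ge=0, le=1)
    brightness_max_fraction: float = Field(0.20, ge=0, le=1)
    noise_std: float = Field(0.01, ge=0)


class TrainBlock(_Strict):
    lr: float = Field(8e-3, gt=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    batch_size: int = Field(16, ge=1)
    epochs: int = Field(250, ge=1)
    folds: int = Field(5, ge=2)
    val_interval: int = Field(5, ge=1)
    max_restarts: int = Field(0, ge=0)


class StapleBlock(_Strict):
    tol: float = Field(1e-7, gt=0)
    max_iter: int = Field(100, ge=1)


class XaiBlock(_Strict):
    layer: str = "OUT"
    aggregation: str = "predicted-pixels"
    score_source: str = "logit"


class EvalBlock(_Strict):
    hd95_mode: str = "pooled"


class RunConfig(_Strict):
    seed: int = 0
    output_root: str = "runs"
    data: DataBlock = Field(default_factory=DataBlock)
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    augment: AugmentBlock = Field(default_factory=AugmentBlock)
    staple: StapleBlock = Field(default_factory=StapleBlock)
    xai: XaiBlock = Field(default_factory=XaiBlock)
    eval: EvalBlock = Field(default_factory=EvalBlock)

    @classmethod
    def load(cls, path: Path | str) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def dump(self, path: Path | str):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()).hexdigest()[:12]

    def derive_seed(self, stage: str) -> int:
        """Fan the global seed out to a per-stage stream via stable hashing."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)
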