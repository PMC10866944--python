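"""Hybrid CNN-Transformer encoder-decoder for 4-class glioma segmentation.

A U-shaped convolutional network whose bottleneck is a stack of pre-norm
vision-transformer blocks.  The encoder has four double-conv blocks
(conv3x3 -> BN -> ReLU, twice) with channel widths K, 2K, 4K, 8K and three
2x2 max-poolings, so the bottleneck grid is H/8 x W/8.  Bottleneck features
are embedded into tokens (one per PxP patch of the feature grid, learned
positional embeddings added), passed through L transformer blocks
(z' = MSA(LN(z)) + z ; z = MLP(LN(z')) + z'), restored to a spatial grid by
a learned projection, and decoded by three 2x2-stride-2 transposed
convolutions with encoder skip concatenation.  A 1x1 convolution and a
per-pixel softmax produce the 4-class probability map.

Internal layers carry stable tags (EB1..EB4, BOT, DB1..DB4, OUT) used by the
saliency generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d2x2,
    Module,
    SGD,  # noqa: F401  (re-exported convenience)
    Tensor,
    TransformerBlock,
    concat,
    maxpool2d_2x2,
)
from .nn.modules import Linear, _trunc_normal

LAYER_TAGS = ("EB1", "EB2", "EB3", "EB4", "BOT", "DB1", "DB2", "DB3", "DB4", "OUT")


@dataclass
class TransformerConfig:
    num_blocks: int = 4
    num_heads: int = 8
    embed_dim: int = 256
    mlp_dim: int = 1024
    patch_size: int = 1


@dataclass
class ModelConfig:
    in_channels: int = 4
    num_classes: int = 4
    base_filters: int = 32
    encoder_levels: int = 4  # 3 poolings -> H/8 bottleneck
    input_size: tuple[int, int] = (192, 192)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    #: optional class prior for the classifier-head bias (bias = log prior).
    #: Starting the head at the class frequencies keeps cross-entropy from
    #: driving the network into a background-only collapse on very
    #: imbalanced data.  None = zero bias (uniform initial prediction).
    head_bias_prior: tuple[float, ...] | None = None

    def __post_init__(self):
        if isinstance(self.transformer, dict):
            self.transformer = TransformerConfig(**self.transformer)
        if self.head_bias_prior is not None:
            self.head_bias_prior = tuple(float(p) for p in self.head_bias_prior)
            if len(self.head_bias_prior) != self.num_classes or min(self.head_bias_prior) <= 0:
                raise ValueError("head_bias_prior needs one positive entry per class")
        h, w = self.input_size
        p = self.transformer.patch_size
        if h % (8 * p) or w % (8 * p):
            raise ValueError(f"input size {h}x{w} must be divisible by 8*patch_size={8 * p}")
        if self.base_filters < 1 or self.transformer.num_blocks < 1:
            raise ValueError("base_filters and num_blocks must be >= 1")

    @property
    def bottleneck_size(self) -> tuple[int, int]:
        return self.input_size[0] // 8, self.input_size[1] // 8

    def to_json(self, path: Path | str):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "ModelConfig":
        d = json.loads(Path(path).read_text())
        d["input_size"] = tuple(d["input_size"])
        return cls(**d)


class ConvBlock(Module):
    """[conv3x3 -> BN -> ReLU] x 2."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class PatchEmbed(Module):
    """Tokenize a (N, C, h, w) feature grid into (N, (h/P)(w/P), D) with positions."""

    def __init__(self, in_ch: int, grid: tuple[int, int], patch_size: int, embed_dim: int, rng):
        super().__init__()
        self.p = patch_size
        self.grid = grid
        if grid[0] % patch_size or grid[1] % patch_size:
            raise ValueError(f"feature grid {grid} not divisible by patch size {patch_size}")
        self.tokens_hw = (grid[0] // patch_size, grid[1] // patch_size)
        n_tokens = self.tokens_hw[0] * self.tokens_hw[1]
        self.proj = Linear(in_ch * patch_size * patch_size, embed_dim, rng)
        self.pos = Tensor(_trunc_normal(rng, (n_tokens, embed_dim)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        p = self.p
        th, tw = h // p, w // p
        # (N,C,h,w) -> (N, th, tw, C*p*p) token patches
        t = x.reshape(n, c, th, p, tw, p).transpose((0, 2, 4, 1, 3, 5)).reshape(n, th * tw, c * p * p)
        return self.proj(t) + self.pos


class FeatureRestore(Module):
    """Project tokens back to a (N, C_out, h, w) grid (learned pixel-shuffle).

    For patch size 1 this is exactly a reshape followed by a 1x1 convolution.
    """

    def __init__(self, embed_dim: int, out_ch: int, tokens_hw: tuple[int, int], patch_size: int, rng):
        super().__init__()
        self.p = patch_size
        self.tokens_hw = tokens_hw
        self.out_ch = out_ch
        self.proj = Linear(embed_dim, out_ch * patch_size * patch_size, rng)

    def forward(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        th, tw = self.tokens_hw
        p, c = self.p, self.out_ch
        t = self.proj(z).reshape(n, th, tw, c, p, p)
        return t.transpose((0, 3, 1, 4, 2, 5)).reshape(n, c, th * p, tw * p)


class HybridSegNet(Module):
    """The full encoder-transformer-decoder segmentation network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = cfg.base_filters
        widths = [k * (2 ** i) for i in range(cfg.encoder_levels)]  # K, 2K, 4K, 8K
        self.enc = [ConvBlock(cfg.in_channels if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(cfg.encoder_levels)]
        tcfg = cfg.transformer
        grid = cfg.bottleneck_size
        self.embed = PatchEmbed(widths[-1], grid, tcfg.patch_size, tcfg.embed_dim, rng)
        self.blocks = [TransformerBlock(tcfg.embed_dim, tcfg.num_heads, tcfg.mlp_dim, rng)
                       for _ in range(tcfg.num_blocks)]
        self.restore = FeatureRestore(tcfg.embed_dim, widths[-1], self.embed.tokens_hw, tcfg.patch_size, rng)
        self.bot_block = ConvBlock(widths[-1], widths[-1], rng)  # DB1
        self.ups = [ConvTranspose2d2x2(widths[i + 1], widths[i], rng) for i in reversed(range(3))]
        self.dec = [ConvBlock(2 * widths[i], widths[i], rng) for i in reversed(range(3))]
        self.out_conv = Conv2d(widths[0], cfg.num_classes, 1, rng=rng)
        # moderate classifier-head variance: the untrained network starts
        # near the uniform prediction (initial loss ~ ln C + GD(uniform))
        # but keeps enough per-class asymmetry that the dice term can pull
        # rare classes out of the background-collapse plateau
        self.out_conv.weight.data[...] = _trunc_normal(rng, self.out_conv.weight.shape, std=0.3)
        if cfg.head_bias_prior is not None:
            self.out_conv.bias.data[...] = np.log(np.asarray(cfg.head_bias_prior, dtype=np.float32))

    # ------------------------------------------------------------------ core
    def forward_features(self, x: Tensor) -> tuple[Tensor, dict[str, Tensor]]:
        """Forward pass returning pre-softmax logits and tagged activations."""
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        if h % 8 or w % 8:
            raise ValueError(f"spatial size {h}x{w} must be divisible by 8")
        acts: dict[str, Tensor] = {}
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            acts[f"EB{i + 1}"] = x
            if i < len(self.enc) - 1:
                skips.append(x)
                x = maxpool2d_2x2(x)
        z = self.embed(x)
        for blk in self.blocks:
            z = blk(z)
        x = self.restore(z)
        acts["BOT"] = x
        x = self.bot_block(x)
        acts["DB1"] = x
        for j, (up, dec) in enumerate(zip(self.ups, self.dec)):
            x = up(x)
            skip = skips[-(j + 1)]
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip resolution {skip.shape[2:]} != decoder {x.shape[2:]}")
            x = dec(concat([skip, x], axis=1))
            acts[f"DB{j + 2}"] = x
        logits = self.out_conv(x)
        acts["OUT"] = logits
        return logits, acts

    def forward(self, x: Tensor) -> Tensor:
        """(N, 4, H, W) -> per-pixel class probabilities (N, 4, H, W)."""
        logits, _ = self.forward_features(x)
        return logits.softmax(axis=1)


def softmax_probs(logits: Tensor) -> Tensor:
    return logits.softmax(axis=1)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> HybridSegNet:
    return HybridSegNet(cfg or ModelConfig(), seed=seed)


# ----------------------------------------------------------------- checkpoint
def save_checkpoint(model: HybridSegNet, path: Path | str, extra: dict | None = None):
    """Save weights as .npz with a JSON sidecar recording the ModelConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"model_config": asdict(model.cfg)}
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2, default=str))


def load_checkpoint(path: Path | str) -> HybridSegNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mc = meta["model_config"]
    mc["input_size"] = tuple(mc["input_size"])
    model = HybridSegNet(ModelConfig(**mc))
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model
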