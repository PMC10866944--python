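"""Neural-network modules built on the autodiff tape."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d_2x2, maxpool2d_2x2


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val._named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}.{i}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state["buffer." + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer."):
                bufs[key[len("buffer."):]][...] = arr
            else:
                params[key].data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    a = rng.normal(0.0, std, size=shape)
    np.clip(a, -2 * std, 2 * std, out=a)
    return a.astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.pad = pad if pad is not None else kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class ConvTranspose2d2x2(Module):
    """Transposed conv, kernel 2x2, stride 2 (the decoder up-convolution)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(_he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None, init: str = "trunc"):
        super().__init__()
        rng = rng or np.random.default_rng()
        if init == "trunc":
            w = _trunc_normal(rng, (in_dim, out_dim))
        elif init == "zero":
            w = np.zeros((in_dim, out_dim), dtype=np.float32)
        else:
            w = _he_normal(rng, (in_dim, out_dim), in_dim)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MultiheadSelfAttention(Module):
    """Standard softmax(QK^T/sqrt(d))V attention over (N, T, D) token batches."""

    def __init__(self, embed_dim: int, num_heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        self.num_heads = num_heads
        self.head_dim = embed_dim // num_heads
        self.q = Linear(embed_dim, embed_dim, rng)
        self.k = Linear(embed_dim, embed_dim, rng)
        self.v = Linear(embed_dim, embed_dim, rng)
        self.out = Linear(embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, hd = self.num_heads, self.head_dim

        def split(v: Tensor) -> Tensor:  # (N,T,D) -> (N,h,T,hd)
            return v.reshape(n, t, h, hd).transpose((0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        attn = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(hd))
        attn = attn.softmax(axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(n, t, d)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm residual block: z' = MSA(LN(z)) + z ; out = MLP(LN(z')) + z'."""

    def __init__(self, embed_dim: int, num_heads: int, mlp_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.ln1 = LayerNorm(embed_dim)
        self.msa = MultiheadSelfAttention(embed_dim, num_heads, rng)
        self.ln2 = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, embed_dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.msa(self.ln1(z)) + z
        return self.fc2(self.fc1(self.ln2(z)).relu()) + z


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 8e-3, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


__all__ = [
    "Module", "Conv2d", "ConvTranspose2d2x2", "BatchNorm2d", "LayerNorm",
    "Linear", "MultiheadSelfAttention", "TransformerBlock", "SGD",
    "Tensor", "conv2d", "conv_transpose2d_2x2", "maxpool2d_2x2",
]
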