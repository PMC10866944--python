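"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order, accumulating gradients.  Primitives are implemented at the granularity
of whole layers where that pays (conv2d via im2col + BLAS matmul, 2x2
max-pool, 2x2-stride-2 transposed conv) and as elementwise/reduction ops
elsewhere, so composite layers such as batch normalization are differentiated
by composition rather than by hand-derived formulas.

All floating point work is float32 unless the caller supplies float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "conv_transpose2d_2x2",
    "maxpool2d_2x2",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    a = np.asarray(x)
    if dtype is None and a.dtype.kind != "f":
        a = a.astype(np.float32)
    elif dtype is not None:
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "tag")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.tag: str | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray, shared: bool = False):
        """Add ``grad`` to this tensor's gradient buffer.

        ``shared=True`` marks arrays that may alias another tensor's buffer
        (views, or one array handed to several parents); those are copied
        before being stored so in-place accumulation cannot corrupt them.
        """
        if self.grad is None:
            if shared or grad.dtype != self.data.dtype or not grad.flags.owndata:
                grad = grad.astype(self.data.dtype, copy=True)
            self.grad = grad
        else:
            self.grad += grad

    # ------------------------------------------------------------- op helpers
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward: Callable | None):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if req:
            out = Tensor.__new__(Tensor)
            out.data = data
            out.grad = None
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
            out.tag = None
            return out
        t = Tensor.__new__(Tensor)
        t.data = data
        t.grad = None
        t.requires_grad = False
        t._parents = ()
        t._backward = None
        t.tag = None
        return t

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -------------------------------------------------------------- pointwise
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape), shared=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape), shared=True)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (p * self.data ** (p - 1.0)))

        return Tensor._make(out_data, (self,), backward)

    __pow__ = pow

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient passes where x > lo."""
        mask = self.data > lo
        out_data = np.where(mask, self.data, lo).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis if isinstance(axis, int) else tuple(sorted(axis)))
            self._accumulate(np.broadcast_to(gg, self.shape), shared=True)

        return Tensor._make(np.asarray(out_data), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- structural
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(in_shape), shared=True)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out_data = np.transpose(self.data, axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv), shared=True)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # ----------------------------------------------------------------- linalg
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        return Tensor._make(s, (self,), backward)


# ----------------------------------------------------------------- free ops
def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(out_data, tuple(tensors), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) patch matrix for stride-1 'same' conv.

    Built by slicing the padded input once per kernel offset; every write is
    contiguous, which beats transposing a sliding-window view.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = np.empty((n, c, kh * kw, oh * ow), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            cols[:, :, di * kw + dj, :] = x[:, :, di:di + oh, dj:dj + ow].reshape(n, c, -1)
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - kh + 1, wp - kw + 1
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh * kw, oh, ow)
    for di in range(kh):
        for dj in range(kw):
            out[:, :, di:di + oh, dj:dj + ow] += cols[:, :, di * kw + dj]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(out)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW, weight (O,C,kh,kw)."""
    n, c, h, wd = x.shape
    o, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    oh, ow = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    cols = _im2col(x.data, kh, kw, pad)  # (N, C*kh*kw, L)
    wmat = w.data.reshape(o, -1)
    out = np.matmul(wmat, cols)  # (O, CK) @ (N, CK, L) -> (N, O, L)
    if b is not None:
        out += b.data[:, None]
    out_data = out.reshape(n, o, oh, ow)

    def backward(g):
        g3 = g.reshape(n, o, oh * ow)
        if w.requires_grad:
            gw = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)  # (O, CK)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g3.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, g3)  # (N, CK, L)
            x._accumulate(_col2im(gcols, x.shape, kh, kw, pad))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 transposed convolution with stride 2; weight (C_in, C_out, 2, 2)."""
    n, c, h, wd = x.shape
    cin, cout = w.shape[:2]
    if cin != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input {c}, weight {cin}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,O,2,2)
    out_data = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(n, cout, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gr = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,O,2,2)
        if x.requires_grad:
            gx = np.tensordot(gr, w.data, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,C)
            x._accumulate(gx.transpose(0, 3, 1, 2))
        if w.requires_grad:
            gw = np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2]))  # (C,O,2,2)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def maxpool2d_2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d_2x2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    return Tensor._make(np.ascontiguousarray(out_data), (x,), backward)
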