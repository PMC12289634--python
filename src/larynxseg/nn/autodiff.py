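"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: each :class:`Tensor` records its
parents and a closure that propagates the upstream gradient. Only the
operations required by the segmentation network are provided (broadcasted
arithmetic, batched matmul, reshapes, GELU, softmax, layer norm, strided
convolution, depth-wise 3x3 convolution, bilinear resize, cross-entropy).
All arithmetic is float32.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An n-d float32 array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _tracks(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p._tracks():
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    if _GRAD_ENABLED and any(p._tracks() for p in parents):
        return Tensor(data, parents=tuple(parents), backward=backward)
    return Tensor(data)


# -- elementwise / linear algebra -----------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a._tracks():
            a._accum(_unbroadcast(g, a.shape))
        if b._tracks():
            b._accum(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a._tracks():
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b._tracks():
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)

    def bwd(g):
        if a._tracks():
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b._tracks():
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.shape))

    return _node(out_data, (a, b), bwd)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accum(g.reshape(a.shape))

    return _node(out_data, (a,), bwd)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))

    return _node(out_data, (a,), bwd)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t._tracks():
                t._accum(piece)

    return _node(out_data, tuple(tensors), bwd)


def mean(a: Tensor) -> Tensor:
    out_data = a.data.mean()
    n = a.data.size

    def bwd(g):
        a._accum(np.full(a.shape, g / n, dtype=np.float32))

    return _node(out_data, (a,), bwd)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = x * cdf

    def bwd(g):
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
        a._accum(g * (cdf + x * pdf))

    return _node(out_data.astype(np.float32), (a,), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    return _node(y, (a,), bwd)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the trailing axis, then scale and shift per channel."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data
    n = x.shape[-1]

    def bwd(g):
        if gain._tracks():
            gain._accum(_unbroadcast(g * xhat, gain.shape))
        if bias._tracks():
            bias._accum(_unbroadcast(g, bias.shape))
        if a._tracks():
            gx = g * gain.data
            # d/dx of (x - mu) / sqrt(var + eps)
            gsum = gx.sum(axis=-1, keepdims=True)
            gdot = (gx * xhat).sum(axis=-1, keepdims=True)
            a._accum(inv * (gx - gsum / n - xhat * gdot / n))

    return _node(out_data.astype(np.float32), (a, gain, bias), bwd)


# -- spatial ops -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """Strided 2-d cross-correlation. x: (B,C,H,W), w: (Cout,C,k,k)."""
    B, C, H, W = x.shape
    Cout, _, k, _ = w.shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((B, C, k, k, Ho, Wo), dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di, dj] = xp[:, :, di:di + Ho * stride:stride, dj:dj + Wo * stride:stride]
    cols2 = cols.reshape(B, C * k * k, Ho * Wo)
    wmat = w.data.reshape(Cout, C * k * k)
    out = np.matmul(wmat, cols2).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out += b.data[None, :, None, None]

    def bwd(g):
        gmat = g.reshape(B, Cout, Ho * Wo)
        if w._tracks():
            gw = np.einsum("bop,bcp->oc", gmat, cols2, optimize=True)
            w._accum(gw.reshape(w.shape))
        if b is not None and b._tracks():
            b._accum(g.sum(axis=(0, 2, 3)))
        if x._tracks():
            gcols = np.matmul(wmat.T[None], gmat).reshape(B, C, k, k, Ho, Wo)
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di:di + Ho * stride:stride, dj:dj + Wo * stride:stride] += gcols[:, :, di, dj]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bwd)


def dwconv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Depth-wise 3x3 convolution, stride 1, zero padding 1. w: (C,3,3)."""
    B, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((B, C, H, W), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            out += w.data[None, :, di, dj, None, None] * xp[:, :, di:di + H, dj:dj + W]
    out += b.data[None, :, None, None]

    def bwd(g):
        if w._tracks():
            gw = np.empty_like(w.data)
            for di in range(3):
                for dj in range(3):
                    gw[:, di, dj] = (g * xp[:, :, di:di + H, dj:dj + W]).sum(axis=(0, 2, 3))
            w._accum(gw)
        if b._tracks():
            b._accum(g.sum(axis=(0, 2, 3)))
        if x._tracks():
            gxp = np.zeros_like(xp)
            for di in range(3):
                for dj in range(3):
                    gxp[:, :, di:di + H, dj:dj + W] += w.data[None, :, di, dj, None, None] * g
            x._accum(gxp[:, :, 1:-1, 1:-1])

    return _node(out, (x, w, b), bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (half-pixel-centre convention)."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B,C,H,W) to (B,C,Ho,Wo); a fixed linear map."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    Ah = _interp_matrix(Ho, H)
    Aw = _interp_matrix(Wo, W)
    out = np.einsum("oi,bcij,pj->bcop", Ah, x.data, Aw, optimize=True)

    def bwd(g):
        gx = np.einsum("io,bcop,jp->bcij", Ah.T, g, Aw.T, optimize=True)
        x._accum(gx.astype(np.float32))

    return _node(out.astype(np.float32), (x,), bwd)


def pad2d(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad bottom/right of (B,C,H,W)."""
    out = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
    H, W = x.shape[2], x.shape[3]

    def bwd(g):
        x._accum(g[:, :, :H, :W])

    return _node(out, (x,), bwd)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel multinomial cross-entropy.

    logits: (B, num_classes, H, W); target: (B, H, W) int labels.
    """
    B, C, H, W = logits.shape
    t = np.asarray(target)
    if t.max() >= C:
        raise ValueError(f"target class {t.max()} >= num_classes {C}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    bi, hi, wi = np.ogrid[:B, :H, :W]
    n = B * H * W
    loss = -np.log(np.maximum(p[bi, t, hi, wi], 1e-30)).sum() / n

    def bwd(g):
        gl = p.copy()
        gl[bi, t, hi, wi] -= 1.0
        logits._accum(gl * (g / n))

    return _node(np.float32(loss), (logits,), bwd)
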