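"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray together with an optional gradient
and a backward closure.  Operations build a DAG; :meth:`Tensor.backward`
runs a topological sweep.  The op set is exactly what an inverted-residual
convolutional classifier needs: grouped/depthwise convolution, batch
normalisation, the MobileNet activation family, pooling, slicing/concat and
a fused softmax cross-entropy.  Everything is float32 and deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "add", "sub", "mul", "pow_const", "matmul", "reshape",
    "transpose", "concat", "getitem", "tsum", "tmean", "relu", "gelu",
    "sigmoid", "hardsigmoid", "hardswish", "conv2d", "batch_norm",
    "maxpool2x2", "cross_entropy", "dropout",
]

_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Tensor:
    """A float32 array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr if arr.flags.c_contiguous else np.ascontiguousarray(arr)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data.reshape(()))

    def accumulate(self, g: np.ndarray) -> None:
        # First writer donates its array; later writers allocate a fresh sum
        # so shared upstream buffers are never mutated in place.
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._parents:
                # interior node: its gradient has been consumed; free it
                t.grad = None

    # Sugar used sparingly in model code.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    if live:
        out.requires_grad = True
        out._parents = live
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` to ``shape`` by summing broadcast axes."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(-_unbroadcast(g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def pow_const(a: Tensor, p: float) -> Tensor:
    def backward(g):
        a.accumulate(g * (p * a.data ** (p - 1)))

    return _node(a.data ** p, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a.accumulate(_unbroadcast(ga, a.shape))
        b.accumulate(_unbroadcast(gb, b.shape))

    return _node(a.data @ b.data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a.accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, ax0: int, ax1: int) -> Tensor:
    def backward(g):
        a.accumulate(np.swapaxes(g, ax0, ax1))

    return _node(np.swapaxes(a.data, ax0, ax1), (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def getitem(a: Tensor, idx) -> Tensor:
    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a.accumulate(full)

    return _node(a.data[idx], (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _node(a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32),
                 (a,), backward)


def tmean(a: Tensor, axis, keepdims: bool = True) -> Tensor:
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = float(np.prod([a.data.shape[i] for i in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g / n, a.data.shape).astype(np.float32))

    return _node(a.data.mean(axis=axis, keepdims=keepdims, dtype=np.float32),
                 (a,), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0)

    def backward(g):
        a.accumulate(g * (a.data > 0))

    return _node(out, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    """Exact (error-function) Gaussian Error Linear Unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        a.accumulate((g * (cdf + x * pdf)).astype(np.float32))

    return _node(x * cdf, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a.accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def hardsigmoid(a: Tensor) -> Tensor:
    """relu6(x + 3) / 6 — the MobileNetV3 piecewise-linear sigmoid."""
    x = a.data
    out = np.clip(x / 6.0 + 0.5, 0.0, 1.0).astype(np.float32)

    def backward(g):
        a.accumulate(g * ((x > -3.0) & (x < 3.0)) / np.float32(6.0))

    return _node(out, (a,), backward)


def hardswish(a: Tensor) -> Tensor:
    """x * relu6(x + 3) / 6."""
    x = a.data
    inner = np.clip(x / 6.0 + 0.5, 0.0, 1.0)

    def backward(g):
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, x / 3.0 + 0.5))
        a.accumulate((g * d).astype(np.float32))

    return _node((x * inner).astype(np.float32), (a,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    """(N,C,Hp,Wp) -> (N, C, kh*kw, ho*wo) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh * kw, ho * wo), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            patch = xp[:, :, u:u + stride * ho:stride, v:v + stride * wo:stride]
            cols[:, :, u * kw + v, :] = patch.reshape(n, c, ho * wo)
    return cols


def _depthwise(x: Tensor, w: Tensor, b: Tensor | None, stride: int,
               padding: int, ho: int, wo: int) -> Tensor:
    """Depthwise conv as k*k fused elementwise FMAs (no patch matrix)."""
    n, c, h, wd = x.data.shape
    _, _, kh, kw = w.data.shape
    xp = x.data if padding == 0 else np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    wk = w.data.reshape(c, kh, kw)
    out = np.zeros((n, c, ho, wo), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            out += xp[:, :, u:u + stride * ho:stride,
                      v:v + stride * wo:stride] * wk[:, u, v][:, None, None]
    if b is not None:
        out += b.data.reshape(1, c, 1, 1)

    def backward(g):
        if w.requires_grad:
            gw = np.empty((c, 1, kh, kw), dtype=np.float32)
            for u in range(kh):
                for v in range(kw):
                    patch = xp[:, :, u:u + stride * ho:stride,
                               v:v + stride * wo:stride]
                    gw[:, 0, u, v] = np.einsum("nchw,nchw->c", g, patch,
                                               optimize=True)
            w.accumulate(gw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u:u + stride * ho:stride,
                        v:v + stride * wo:stride] += g * wk[:, u, v][:, None, None]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x.accumulate(gxp)

    return _node(out, (x, w) if b is None else (x, w, b), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation (NCHW, OIHW weights)."""
    n, c, h, wd = x.data.shape
    co, cg, kh, kw = w.data.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: {c} input channels, weight expects "
                         f"{cg}*{groups}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    if groups == c and cg == 1 and co == c and not (kh == kw == 1):
        return _depthwise(x, w, b, stride, padding, ho, wo)
    xp = x.data if padding == 0 else np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cog = co // groups
    if kh == kw == 1 and stride == 1 and padding == 0:
        cols = xp.reshape(n, groups, cg, ho * wo)
    else:
        cols = _im2col(xp, kh, kw, stride, ho, wo).reshape(
            n, groups, cg * kh * kw, ho * wo)
    wmat = w.data.reshape(groups, cog, cg * kh * kw)
    out = np.matmul(wmat, cols).reshape(n, co, ho, wo)
    if b is not None:
        out += b.data.reshape(1, co, 1, 1)

    def backward(g):
        gr = g.reshape(n, groups, cog, ho * wo)
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gr, cols, optimize=True)
            w.accumulate(gw.reshape(co, cg, kh, kw))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.transpose(0, 2, 1), gr)
            dcols = dcols.reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u:u + stride * ho:stride,
                        v:v + stride * wo:stride] += dcols[:, :, u, v]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x.accumulate(gxp)

    return _node(out, (x, w) if b is None else (x, w, b), backward)


# ---------------------------------------------------------------------------
# normalisation / pooling / loss
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, *,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) for NCHW input.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the buffers are used as constants.
    """
    xd = x.data
    if training:
        m = xd.mean(axis=(0, 2, 3), dtype=np.float32)
        v = xd.var(axis=(0, 2, 3), dtype=np.float32)
        n = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * m
        running_var *= (1 - momentum)
        running_var += momentum * v * (n / max(n - 1, 1))
    else:
        m, v = running_mean, running_var
    inv = (1.0 / np.sqrt(v + eps)).astype(np.float32)
    # fused affine: y = x * (gamma*inv) + (beta - m*gamma*inv)
    scale = (gamma.data * inv).reshape(1, -1, 1, 1)
    shift = (beta.data - m * gamma.data * inv).reshape(1, -1, 1, 1)
    out = xd * scale
    out += shift

    def backward(g):
        need_xhat = gamma.requires_grad or (
            training and (x.requires_grad or x._parents))
        if need_xhat:
            xhat = (xd - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        if gamma.requires_grad:
            gamma.accumulate(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            if training:
                cnt = g.shape[0] * g.shape[2] * g.shape[3]
                gm = g.mean(axis=(0, 2, 3), keepdims=True, dtype=np.float32)
                gxm = np.einsum("nchw,nchw->c", g, xhat,
                                optimize=True).reshape(1, -1, 1, 1) / cnt
                x.accumulate(scale * (g - gm - xhat * gxm))
            else:
                x.accumulate(scale * g)

    return _node(out, (x, gamma, beta), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (even spatial dims required)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(gx)

    return _node(out, (x,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()

    def backward(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        logits.accumulate(g * gp / np.float32(n))

    return _node(np.float32(nll), (logits,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep

    def backward(g):
        x.accumulate(g * mask)

    return _node(x.data * mask, (x,), backward)
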