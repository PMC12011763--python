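"""Differentiable operations for the MTL-OCA network.

Every backward pass here is checked against central finite differences in
``tests/test_nn.py``; keep that suite green when touching anything.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "add", "mul", "matmul", "relu", "reshape", "transpose", "concat",
    "sum", "mean", "softmax", "reciprocal", "conv2d", "maxpool2d", "upsample2x",
    "group_norm", "linear", "global_avg_pool", "softmax_cross_entropy",
]


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b) -> Tensor:
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=a.dtype))
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = _bw
    return out


def mul(a: Tensor, b) -> Tensor:
    if isinstance(b, Tensor):
        out = Tensor(a.data * b.data, parents=(a, b))

        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))
    else:
        c = b
        out = Tensor(a.data * c, parents=(a,))

        def _bw(g):
            if a.requires_grad:
                a._accumulate(g * c)

    out._backward = _bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D or batched (leading-dim broadcast-free) matrix product."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    out._backward = _bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0), parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = _bw
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = _bw
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = _bw
    return out


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


def sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def _bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    out._backward = _bw
    return out


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data
    out = Tensor(inv, parents=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(-g * inv * inv)

    out._backward = _bw
    return out


def softmax(a: Tensor, axis: int) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(a,))

    def _bw(g):
        if a.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate((g - dot) * y)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Cross-correlation with 'same' zero padding, stride 1.

    x: (N, C, H, W); w: (O, C, kh, kw) with odd kh == kw; b: (O,).

    Implemented as kh*kw shifted GEMMs on a channels-last copy, which is
    several times faster than im2col for the sizes this network uses.
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    pad = kh // 2
    xt = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))  # NHWC
    if pad:
        xp = np.pad(xt, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    else:
        xp = xt
    wt = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0))  # (kh, kw, C, O)
    y = np.zeros((n * h * wd, o), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, i:i + h, j:j + wd, :].reshape(-1, c)
            y += xs @ wt[i, j]
    if b is not None:
        y += b.data
    y = np.ascontiguousarray(y.reshape(n, h, wd, o).transpose(0, 3, 1, 2))
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def _bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            gw = np.empty_like(wt)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, i:i + h, j:j + wd, :].reshape(-1, c)
                    gw[i, j] = xs.T @ gmat
            w._accumulate(gw.transpose(3, 2, 0, 1))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + h, j:j + wd, :] += (gmat @ wt[i, j].T).reshape(n, h, wd, c)
            if pad:
                gxp = gxp[:, pad:-pad, pad:-pad, :]
            x._accumulate(np.ascontiguousarray(gxp.transpose(0, 3, 1, 2)))

    out._backward = _bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(n, c, h, w))

    out._backward = _bw
    return out


_UPSAMPLE_CACHE: dict[tuple[int, type], np.ndarray] = {}


def _upsample_matrix(n_in: int, dtype) -> np.ndarray:
    """(2n, n) bilinear x2 interpolation matrix (half-pixel centers)."""
    key = (n_in, np.dtype(dtype).name)
    mat = _UPSAMPLE_CACHE.get(key)
    if mat is None:
        mat = np.zeros((2 * n_in, n_in), dtype=dtype)
        for o in range(2 * n_in):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            t = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            mat[o, i0c] += 1.0 - t
            mat[o, i1c] += t
        _UPSAMPLE_CACHE[key] = mat
    return mat


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of (N,C,H,W)."""
    n, c, h, w = x.shape
    uh = _upsample_matrix(h, x.dtype)
    uw = _upsample_matrix(w, x.dtype)
    y = uh @ x.data @ uw.T
    out = Tensor(y, parents=(x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(uh.T @ g @ uw)

    out._backward = _bw
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """GroupNorm over (N,C,H,W); gamma/beta shaped (C,)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = x.data.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    gamma_b = gamma.data.reshape(1, c, 1, 1)
    y = xhat * gamma_b + beta.data.reshape(1, c, 1, 1)
    out = Tensor(y, parents=(x, gamma, beta))

    def _bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma_b).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xh).mean(axis=2, keepdims=True)
            dx = (dxhat - m1 - xh * m2) * inv
            x._accumulate(dx.reshape(n, c, h, w))

    out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return mean(x, axis=(2, 3))


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy with integer targets.

    logits: (N, K) or (N, K, H, W); targets: (N,) or (N, H, W) ints in [0, K).
    """
    t = np.asarray(targets)
    if logits.ndim == 4:
        k = logits.shape[1]
        z = logits.data.transpose(0, 2, 3, 1).reshape(-1, k)
        ti = t.reshape(-1).astype(np.int64)
    else:
        k = logits.shape[1]
        z = logits.data
        ti = t.reshape(-1).astype(np.int64)
    if ti.min() < 0 or ti.max() >= k:
        raise ValueError(f"targets out of range [0, {k})")
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    lse = np.log(ez.sum(axis=1)) + zmax[:, 0]
    nll = lse - z[np.arange(z.shape[0]), ti]
    out = Tensor(np.asarray(nll.mean(), dtype=logits.dtype), parents=(logits,))

    def _bw(g):
        if not logits.requires_grad:
            return
        p = ez / ez.sum(axis=1, keepdims=True)
        p[np.arange(p.shape[0]), ti] -= 1.0
        p *= float(g) / p.shape[0]
        if logits.ndim == 4:
            n, _, h, w = logits.shape
            gl = p.reshape(n, h, w, k).transpose(0, 3, 1, 2)
        else:
            gl = p
        logits._accumulate(gl.astype(logits.dtype))

    out._backward = _bw
    return out
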