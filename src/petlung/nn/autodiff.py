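"""A small reverse-mode autodiff engine over NumPy arrays.

Supports exactly the operations the 3D classifiers need: 3D convolution
(im2col), batch normalization, ReLU, elementwise add, nearest-neighbour
upsampling, global average pooling, linear layers, channel concatenation and
softmax cross-entropy.  Float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor",
    "Parameter",
    "conv3d",
    "relu",
    "add",
    "upsample_nearest",
    "global_avg_pool",
    "linear",
    "batchnorm",
    "concat",
    "cross_entropy_logits",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._grad_fn = grad_fn

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._grad_fn is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._grad_fn(t.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int):
    n, c, d, h, w = xp.shape
    do = (d - k) // stride + 1
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s = xp.strides
    view = as_strided(
        xp,
        shape=(n, c, k, k, k, do, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[4], s[2] * stride, s[3] * stride, s[4] * stride),
    )
    cols = np.ascontiguousarray(view).reshape(n, c * k**3, do * ho * wo)
    return cols, (do, ho, wo)


def _col2im(dcols: np.ndarray, padded_shape, k: int, stride: int, out_sizes):
    n, c, dp, hp, wp = padded_shape
    do, ho, wo = out_sizes
    dx = np.zeros(padded_shape, dtype=np.float32)
    dcols = dcols.reshape(n, c, k, k, k, do, ho, wo)
    for a in range(k):
        for b in range(k):
            for g in range(k):
                dx[
                    :, :,
                    a : a + stride * do : stride,
                    b : b + stride * ho : stride,
                    g : g + stride * wo : stride,
                ] += dcols[:, :, a, b, g]
    return dx


def conv3d(x: Tensor, w: Parameter, b: Parameter | None, stride: int = 1, pad: int = 1) -> Tensor:
    """3D convolution, kernel (Cout, Cin, k, k, k), symmetric padding."""
    cout, cin, k, _, _ = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    cols, (do, ho, wo) = _im2col(xp, k, stride)
    w2 = w.data.reshape(cout, -1)
    out = np.einsum("oc,ncl->nol", w2, cols, optimize=True)
    if b is not None:
        out += b.data[None, :, None]
    n = x.data.shape[0]
    out = out.reshape(n, cout, do, ho, wo)
    padded_shape = xp.shape

    def grad_fn(g):
        g2 = g.reshape(n, cout, -1)
        dw = np.einsum("nol,ncl->oc", g2, cols, optimize=True).reshape(w.data.shape)
        db = g2.sum(axis=(0, 2)) if b is not None else None
        dcols = np.einsum("oc,nol->ncl", w2, g2, optimize=True)
        dxp = _col2im(dcols, padded_shape, k, stride, (do, ho, wo))
        dx = dxp[:, :, pad : dxp.shape[2] - pad or None, pad : dxp.shape[3] - pad or None,
                 pad : dxp.shape[4] - pad or None] if pad else dxp
        grads = [dx, dw]
        if b is not None:
            grads.append(db)
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, grad_fn)


# ---------------------------------------------------------------------------
# pointwise / shape ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: [g * mask])


def add(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError(f"add shape mismatch: {x.data.shape} vs {y.data.shape}")
    return Tensor(x.data + y.data, (x, y), lambda g: [g, g])


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Repeat each voxel ``factor`` times along each spatial axis."""
    f = int(factor)
    out = np.repeat(np.repeat(np.repeat(x.data, f, axis=2), f, axis=3), f, axis=4)

    def grad_fn(g):
        n, c, d, h, w = x.data.shape
        g6 = g.reshape(n, c, d, f, h, f, w, f)
        return [g6.sum(axis=(3, 5, 7))]

    return Tensor(out, (x,), grad_fn)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial maximum."""
    n, c = x.data.shape[:2]
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=2)
    rows, cols = np.arange(n)[:, None], np.arange(c)[None, :]
    out = flat[rows, cols, idx]

    def grad_fn(g):
        dflat = np.zeros_like(flat)
        dflat[rows, cols, idx] = g
        return [dflat.reshape(x.data.shape)]

    return Tensor(out, (x,), grad_fn)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    n, c, d, h, w = x.data.shape
    vol = d * h * w
    out = x.data.reshape(n, c, -1).mean(axis=2)

    def grad_fn(g):
        return [np.broadcast_to(g[:, :, None, None, None] / vol, x.data.shape)]

    return Tensor(out, (x,), grad_fn)


def linear(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """(N, C) @ (C, K) + (K,)"""
    out = x.data @ w.data + b.data

    def grad_fn(g):
        return [g @ w.data.T, x.data.T @ g, g.sum(axis=0)]

    return Tensor(out, (x, w, b), grad_fn)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return np.split(g, splits, axis=axis)

    return Tensor(data, tuple(tensors), grad_fn)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    Updates ``running_mean``/``running_var`` in place when training.
    """
    axes = (0, 2, 3, 4)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    sh = (1, -1, 1, 1, 1)
    xhat = (x.data - mean.reshape(sh)) * inv_std.reshape(sh)
    out = gamma.data.reshape(sh) * xhat + beta.data.reshape(sh)
    m = x.data.size // x.data.shape[1]

    def grad_fn(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        if not training:
            dx = g * (gamma.data * inv_std).reshape(sh)
        else:
            gxhat = g * gamma.data.reshape(sh)
            dx = (
                gxhat
                - gxhat.mean(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
            ) * inv_std.reshape(sh)
        return [dx, dgamma, dbeta]

    return Tensor(out, (x, gamma, beta), grad_fn)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy_logits(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted softmax cross-entropy, mean over the batch."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    w = np.ones(n, dtype=np.float32) if class_weights is None else class_weights[labels]
    wsum = w.sum()
    logp = np.log(probs[np.arange(n), labels] + 1e-12)
    loss = -(w * logp).sum() / wsum

    def grad_fn(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        d *= (w / wsum)[:, None]
        return [g * d]

    return Tensor(loss, (logits,), grad_fn)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
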