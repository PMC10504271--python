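"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network needs a short list of differentiable operations
(dense and depthwise convolution, batch normalisation, channel gating,
linear layers, spatial gathers and a softmax cross-entropy head).  This
module provides exactly those as a small tape-based autodiff engine:
every operation returns a :class:`Tensor` holding the forward value and a
closure that routes gradients to its parents.  ``backward`` walks the tape
in reverse topological order.

All activations are float32; gradients share the dtype of the data.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference): ops return bare tensors."""
    global _GRAD_ENABLED
    prev, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # own copy: g may alias a child's grad buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # single-use tape: break the node->closure->node reference cycles
        # so intermediate arrays are freed without waiting for gc
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._parents = ()
                node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if not _GRAD_ENABLED:
        return out
    live = [p for p in parents if p.requires_grad or p._parents]
    if live:
        out.requires_grad = True
        out._parents = tuple(live)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# FLOP metering: ops report multiply-accumulate counts into an active meter.

_METER: list[dict] | None = None


@contextlib.contextmanager
def flop_meter():
    """Context manager collecting per-op MAC counts from conv/linear ops."""
    global _METER
    prev, _METER = _METER, []
    try:
        yield _METER
    finally:
        _METER = prev


def _record_macs(kind: str, macs: int) -> None:
    if _METER is not None:
        _METER.append({"kind": kind, "macs": int(macs)})


# ---------------------------------------------------------------------------
# Elementwise / linear algebra

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward():
        g = out.grad
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g, b.shape))

    out = _node(out_data, (a, b), backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward():
        g = out.grad
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    out = _node(out_data, (a, b), backward)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (M,K) @ (K,N)."""
    out_data = a.data @ b.data
    _record_macs("matmul", a.data.shape[0] * a.data.shape[1] * b.data.shape[1])

    def backward():
        g = out.grad
        if a.requires_grad or a._parents:
            a.accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b.accumulate(a.data.T @ g)

    out = _node(out_data, (a, b), backward)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _node(x.data * mask, (x,), lambda: x.accumulate(out.grad * mask))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,), lambda: x.accumulate(out.grad * s * (1.0 - s)))
    return out


def swish(x: Tensor) -> Tensor:
    """Sigmoid-weighted linear unit x * sigma(x)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def backward():
        x.accumulate(out.grad * (s + out_data * (1.0 - s)))

    out = _node(out_data, (x,), backward)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = _node(
        x.data.reshape(shape),
        (x,),
        lambda: x.accumulate(out.grad.reshape(x.shape)),
    )
    return out


def moveaxis(x: Tensor, src: int, dst: int) -> Tensor:
    out = _node(
        np.ascontiguousarray(np.moveaxis(x.data, src, dst)),
        (x,),
        lambda: x.accumulate(np.moveaxis(out.grad, dst, src)),
    )
    return out


def concat(xs: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [x.data for x in xs]
    out_data = np.concatenate(datas, axis=axis)
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def backward():
        parts = np.split(out.grad, splits, axis=axis)
        for x, g in zip(xs, parts):
            if x.requires_grad or x._parents:
                x.accumulate(g)

    out = _node(out_data, tuple(xs), backward)
    return out


# ---------------------------------------------------------------------------
# Convolutions ("same" padding in the TensorFlow sense: ceil(side/stride))

def same_padding(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """NCHW convolution with same-padding, via im2col.

    ``w`` has shape (C_out, C_in, k, k); ``b`` (C_out,) or None.
    """
    n, c, h, wd = x.shape
    c_out, c_in, k, _ = w.shape
    pt, pb = same_padding(h, k, stride)
    pl, pr = same_padding(wd, k, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    if k == 1 and stride == 1:
        cols = xp.reshape(n, c, ho * wo)
    else:
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
        cols = np.ascontiguousarray(np.moveaxis(win, (4, 5), (2, 3)))
        cols = cols.reshape(n, c * k * k, ho * wo)
    w2 = w.data.reshape(c_out, c_in * k * k)
    out_data = np.matmul(w2, cols).reshape(n, c_out, ho, wo)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    _record_macs("conv2d", n * c_out * c_in * k * k * ho * wo)

    def backward():
        g = out.grad.reshape(n, c_out, ho * wo)
        if w.requires_grad:
            w.accumulate(
                np.einsum("nol,nkl->ok", g, cols, optimize=True).reshape(w.shape)
            )
        if b is not None and b.requires_grad:
            b.accumulate(out.grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = np.matmul(w2.T, g)  # n, c*k*k, L
            dxp = np.zeros_like(xp)
            d = dcols.reshape(n, c, k, k, ho, wo)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + stride * ho : stride,
                        j : j + stride * wo : stride] += d[:, :, i, j]
            x.accumulate(dxp[:, :, pt : pt + h, pl : pl + wd])

    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents, backward)
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1) -> Tensor:
    """Per-channel convolution; ``w`` has shape (C, k, k)."""
    n, c, h, wd = x.shape
    _, k, _ = w.shape
    pt, pb = same_padding(h, k, stride)
    pl, pr = same_padding(wd, k, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    out_data = np.zeros((n, c, ho, wo), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            out_data += (
                xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                * w.data[None, :, i, j, None, None]
            )
    _record_macs("depthwise_conv2d", n * c * k * k * ho * wo)

    def backward():
        g = out.grad
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, :, i : i + stride * ho : stride,
                            j : j + stride * wo : stride]
                    dw[:, i, j] = np.einsum("nchw,nchw->c", g, sl, optimize=True)
            w.accumulate(dw)
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + stride * ho : stride,
                        j : j + stride * wo : stride] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            x.accumulate(dxp[:, :, pt : pt + h, pl : pl + wd])

    out = _node(out_data, (x, w), backward)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward():
        x.accumulate(
            np.broadcast_to(out.grad[:, :, None, None] / (h * w), x.shape).copy()
        )

    out = _node(out_data, (x,), backward)
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    Running statistics (biased variance) are updated in place in training
    mode so checkpoints capture them.
    """
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward():
        g = out.grad
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad or x._parents:
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gm = g.mean(axis=axes)[None, :, None, None]
                gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
                x.accumulate(gi * (g - gm - xhat * gxm))
            else:
                x.accumulate(gi * g)

    out = _node(out_data, (x, gamma, beta), backward)
    return out


def take_spatial(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather x[:, :, rows[q], cols[q]] -> (N, C, Q); scatter-add backward."""
    n, c, h, w = x.shape
    flat = (rows.astype(np.int64) * w + cols.astype(np.int64))
    xf = x.data.reshape(n, c, h * w)
    out_data = np.ascontiguousarray(xf[:, :, flat])

    def backward():
        q = flat.shape[0]
        g = out.grad.reshape(n * c, q)
        base = np.arange(n * c, dtype=np.int64)[:, None] * (h * w)
        idx = (base + flat[None, :]).ravel()
        dxf = np.bincount(idx, weights=g.ravel().astype(np.float64),
                          minlength=n * c * h * w)
        x.accumulate(dxf.reshape(x.shape).astype(DTYPE))

    out = _node(out_data, (x,), backward)
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean negative log-softmax probability of the true class.

    ``logits`` is (M, K); ``labels`` integer (M,).  Optional per-class
    weights rescale each pixel's contribution (weighted mean).
    """
    z = logits.data
    m = z.max(axis=1, keepdims=True)
    ez = np.exp(z - m)
    sm = ez / ez.sum(axis=1, keepdims=True)
    idx = np.arange(z.shape[0])
    logp = (z - m) - np.log(ez.sum(axis=1, keepdims=True))
    nll = -logp[idx, labels]
    if class_weights is None:
        loss = nll.mean()
        scale = np.full(z.shape[0], 1.0 / z.shape[0], dtype=DTYPE)
    else:
        wpix = class_weights[labels].astype(DTYPE)
        loss = float((nll * wpix).sum() / wpix.sum())
        scale = wpix / wpix.sum()

    def backward():
        g = sm.copy()
        g[idx, labels] -= 1.0
        g *= scale[:, None]
        logits.accumulate(g.astype(DTYPE) * out.grad)

    out = _node(np.asarray(loss, dtype=DTYPE), (logits,), backward)
    return out
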