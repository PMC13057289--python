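"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: every operation the LeafFusionNet architecture
needs (dense/conv/pool/attention/normalisation arithmetic) is a primitive
with a hand-written vector-Jacobian product.  Tensors wrap ``numpy`` arrays
in NHWC layout; the graph is built eagerly and freed after ``backward``.

Gradients are accumulated on *every* node reached during the backward walk,
not only on leaves — Grad-CAM reads the gradient of an intermediate feature
map, so intermediate ``.grad`` must survive.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus (optionally) a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, n):
        return power(self, n)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data, parents, backward):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        live = tuple(p.requires_grad for p in parents)
        out._backward = lambda g, bw=backward, lv=live: bw(g, lv)
    return out


# ---------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, live):
        if live[0]:
            a._accum(_unbroadcast(g, a.shape))
        if live[1]:
            b._accum(_unbroadcast(g, b.shape))

    return _result(a.data + b.data, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, live):
        if live[0]:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if live[1]:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _result(a.data * b.data, (a, b), bw)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, live):
        if live[0]:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if live[1]:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _result(a.data / b.data, (a, b), bw)


def power(a, n: float):
    a = as_tensor(a)

    def bw(g, live):
        a._accum(g * n * a.data ** (n - 1))

    return _result(a.data ** n, (a,), bw)


def texp(a):
    a = as_tensor(a)
    out = np.exp(a.data)

    def bw(g, live):
        a._accum(g * out)

    return _result(out, (a,), bw)


def tlog(a):
    a = as_tensor(a)

    def bw(g, live):
        a._accum(g / a.data)

    return _result(np.log(a.data), (a,), bw)


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)

    def bw(g, live):
        a._accum(g * 0.5 / out)

    return _result(out, (a,), bw)


# ---------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------

def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def bw(g, live):
        a._accum(g * mask)

    return _result(np.where(mask, a.data, 0.0), (a,), bw)


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g, live):
        a._accum(g * out * (1.0 - out))

    return _result(out, (a,), bw)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a):
    """tanh-approximation GELU."""
    a = as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out = 0.5 * x * (1.0 + t)

    def bw(g, live):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
        a._accum(g * da)

    return _result(out, (a,), bw)


def softmax(a, axis: int = -1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g, live):
        a._accum(out * (g - (g * out).sum(axis=axis, keepdims=True)))

    return _result(out, (a,), bw)


# ---------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)

    def bw(g, live):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.shape).astype(a.dtype))

    return _result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    count = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])

    def bw(g, live):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.shape).astype(a.dtype) / count)

    return _result(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)


def reshape(a, shape):
    a = as_tensor(a)

    def bw(g, live):
        a._accum(g.reshape(a.shape))

    return _result(a.data.reshape(shape), (a,), bw)


def transpose(a, axes):
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))

    def bw(g, live):
        a._accum(g.transpose(inv))

    return _result(a.data.transpose(axes), (a,), bw)


def getitem(a, idx):
    a = as_tensor(a)

    def bw(g, live):
        z = np.zeros_like(a.data)
        np.add.at(z, idx, g)
        a._accum(z)

    return _result(a.data[idx], (a,), bw)


def concat(tensors, axis: int = -1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, live):
        for t, lo, hi, lv in zip(tensors, offsets[:-1], offsets[1:], live):
            if lv:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _result(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# ---------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, live):
        if live[0]:
            da = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(da, a.shape))
        if live[1]:
            db = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(db, b.shape))

    return _result(a.data @ b.data, (a, b), bw)


# ---------------------------------------------------------------------
# convolution and pooling (NHWC, stride 1, odd kernel, zero "same" pad)
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B,H,W,C) -> (B,H,W, kh*kw*C) columns with zero same-padding."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (B,H,W,C,kh,kw)
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (B,H,W,kh,kw,C)
    b, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win).reshape(b, h, w, kh * kw * x.shape[3])


def conv2d_same(x, w, bias=None):
    """2-D cross-correlation, stride 1, zero padding preserving H and W.

    x: (B,H,W,Cin); w: (kh,kw,Cin,Cout); bias: (Cout,) or None.

    Computed as a sum of kh*kw shifted (B*H*W, Cin) @ (Cin, Cout) matmuls —
    same arithmetic as im2col but without materialising the column matrix,
    which is the memory-bandwidth bottleneck for wide inputs.
    """
    x, w = as_tensor(x), as_tensor(w)
    kh, kw, cin, cout = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {kh}x{kw}")
    b, h, wd, _ = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((b * h * wd, cout), dtype=x.data.dtype)
    for u in range(kh):
        for v in range(kw):
            shift = np.ascontiguousarray(xp[:, u:u + h, v:v + wd, :])
            out += shift.reshape(-1, cin) @ w.data[u, v]
    out = out.reshape(b, h, wd, cout)
    parents = [x, w]
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data
        parents.append(bias)

    def bw(g, live):
        gflat = g.reshape(-1, cout)
        if live[1]:
            gw = np.empty_like(w.data)
            for u in range(kh):
                for v in range(kw):
                    shift = np.ascontiguousarray(xp[:, u:u + h, v:v + wd, :])
                    gw[u, v] = shift.reshape(-1, cin).T @ gflat
            w._accum(gw)
        if live[0]:
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, u:u + h, v:v + wd, :] += (
                        gflat @ w.data[u, v].T).reshape(b, h, wd, cin)
            x._accum(dxp[:, ph:ph + h, pw:pw + wd, :])
        if bias is not None and live[2]:
            bias._accum(g.sum(axis=(0, 1, 2)))

    return _result(out, tuple(parents), bw)


def maxpool2x2(x):
    """2x2 max pooling, stride 2. Requires even spatial sides."""
    x = as_tensor(x)
    b, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial sides, got {h}x{w}")
    win = x.data.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    win = np.ascontiguousarray(win).reshape(b, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g, live):
        gz = np.zeros_like(win)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        gz = gz.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x._accum(np.ascontiguousarray(gz).reshape(b, h, w, c))

    return _result(out, (x,), bw)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def cross_entropy_with_logits(logits, labels):
    """Mean sparse categorical cross-entropy, stabilised via log-sum-exp.

    logits: (B,K); labels: (B,) integer class ids.
    """
    logits = as_tensor(logits)
    y = np.asarray(labels, dtype=np.int64)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    n = z.shape[0]
    loss = (lse - z[np.arange(n), y]).mean()

    def bw(g, live):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), y] -= 1.0
        logits._accum(g * p / n)

    return _result(np.asarray(loss), (logits,), bw)
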