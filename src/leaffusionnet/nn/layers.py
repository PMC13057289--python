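"""Neural-network layers built on the autodiff primitives.

Initialisation conventions: truncated normal (std 0.02) for dense/embedding
weights, Kaiming-uniform for convolution kernels, zero biases.  Every layer
takes an ``numpy.random.Generator`` at construction so model builds are
fully seed-determined.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .module import Module
from .tensor import Tensor

DTYPE = np.float32


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) resampled into [-2 std, 2 std]."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "trunc_normal"):
        super().__init__()
        if init == "trunc_normal":
            w = trunc_normal(rng, (d_in, d_out))
        else:
            w = kaiming_uniform(rng, (d_in, d_out), fan_in=d_in)
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        return T.matmul(x, self.W) + self.b

    __call__ = forward


class Conv2d(Module):
    """Stride-1 'same' 2-D convolution layer, NHWC."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        fan_in = ksize * ksize * c_in
        self.W = Tensor(kaiming_uniform(rng, (ksize, ksize, c_in, c_out), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        return T.conv2d_same(x, self.W, self.b)

    __call__ = forward


class BatchNorm1d(Module):
    """Batch normalisation over the batch axis.

    Inference statistics are *recalibrated* rather than tracked by a running
    EMA: ``recalibrate_batchnorm`` accumulates exact feature moments over a
    calibration set with frozen weights.  On near-duplicate inputs the
    cross-sample feature variance can be orders of magnitude below the
    feature scale, and an EMA under drifting weights is too noisy at that
    precision; exact moments are not.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(dim, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(dim, dtype=DTYPE))
        self.momentum = momentum
        self.eps = eps
        self._calibrating = False
        self._acc = None

    def begin_calibration(self):
        self._calibrating = True
        self._acc = [0.0, 0.0, 0]  # sum, sum of squares, count

    def finish_calibration(self):
        s, s2, n = self._acc
        if n > 0:
            mean = s / n
            self.running_mean[...] = mean.astype(DTYPE)
            self.running_var[...] = np.maximum(s2 / n - mean ** 2, 0.0).astype(DTYPE)
        self._calibrating = False
        self._acc = None

    def forward(self, x):
        if self.training:
            mu = T.tmean(x, axis=0, keepdims=True)
            xc = x - mu
            var = T.tmean(xc * xc, axis=0, keepdims=True)
            xhat = xc * T.power(var + self.eps, -0.5)
            if self._calibrating:
                xd = x.data if isinstance(x, Tensor) else x
                self._acc[0] += xd.astype(np.float64).sum(axis=0)
                self._acc[1] += (xd.astype(np.float64) ** 2).sum(axis=0)
                self._acc[2] += xd.shape[0]
            else:
                m = self.momentum
                self.running_mean *= 1 - m
                self.running_mean += m * mu.data[0].astype(DTYPE)
                self.running_var *= 1 - m
                self.running_var += m * var.data[0].astype(DTYPE)
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta

    __call__ = forward


class Dropout(Module):
    """Inverted dropout. The generator is (re)assigned by the trainer so
    that interrupted runs resume with identical masks."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must lie in [0,1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep.astype(x.data.dtype))

    __call__ = forward


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = T.tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = T.tmean(xc * xc, axis=-1, keepdims=True)
        return xc * T.power(var + self.eps, -0.5) * self.gamma + self.beta

    __call__ = forward


def recalibrate_batchnorm(model: Module, forward, X: np.ndarray,
                          batch_size: int = 128, max_samples: int = 512) -> None:
    """Recompute BatchNorm inference statistics with frozen weights.

    Runs ``forward(batch)`` (train-mode semantics, dropout suppressed)
    over up to ``max_samples`` of ``X`` while each BatchNorm accumulates
    exact first and second moments of its input, then installs them as the
    inference statistics.  Large calibration batches keep the within-pass
    batch statistics close to the installed global ones.
    """
    from .tensor import no_grad

    bns = [m for m in model.modules() if isinstance(m, BatchNorm1d)]
    if not bns:
        return
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    saved_p = [d.p for d in drops]
    for d in drops:
        d.p = 0.0
    for bn in bns:
        bn.begin_calibration()
    try:
        Xc = X[:max_samples]
        with no_grad():
            for i in range(0, len(Xc), batch_size):
                forward(Xc[i:i + batch_size])
    finally:
        for bn in bns:
            bn.finish_calibration()
        for d, p in zip(drops, saved_p):
            d.p = p


def seed_dropout(model: Module, rng_seed) -> None:
    """Give every Dropout in ``model`` an independent, deterministic stream."""
    ss = np.random.SeedSequence(rng_seed)
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    for m, child in zip(drops, ss.spawn(len(drops))):
        m.rng = np.random.default_rng(child)
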