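"""Fixed Gabor filter bank applied as a zero-parameter depthwise layer.

A Gabor kernel is a sinusoidal carrier under a Gaussian envelope,

    g(x, y) = exp(-1/2 * (x_th^2 + gamma^2 * y_th^2) / sigma^2)
              * cos(2*pi*x_th / lam + psi)

with rotated coordinates x_th = x cos(theta) + y sin(theta) and
y_th = -x sin(theta) + y cos(theta).  ``x`` is the column offset and ``y``
the row offset, both centred on the kernel midpoint.  A bank of such
kernels at several orientations (and optionally several wavelengths) is
cross-correlated with every input channel independently — a depthwise
filter with no trainable parameters — producing a texture-enhanced
multi-channel image for the CNN branch.  Lesion boundaries, streaks and
mottling are orientation- and frequency-specific, which is exactly the
structure these kernels respond to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_N_ORIENTATIONS = 8
DEFAULT_LAMBDA = 4.0
DEFAULT_SIGMA = 2.0
DEFAULT_GAMMA = 0.5
DEFAULT_PSI = 0.0
DEFAULT_KSIZE = 7


@dataclass(frozen=True)
class GaborParams:
    """Analytic parameters of one Gabor kernel.

    theta: orientation (radians, stored modulo 2*pi)
    lam:   wavelength of the carrier (pixels per cycle), > 0
    sigma: std of the Gaussian envelope (pixels), > 0
    gamma: spatial aspect ratio of the envelope, > 0
    psi:   phase offset (radians)
    ksize: odd kernel side length (pixels), >= 3
    """

    theta: float
    lam: float = DEFAULT_LAMBDA
    sigma: float = DEFAULT_SIGMA
    gamma: float = DEFAULT_GAMMA
    psi: float = DEFAULT_PSI
    ksize: int = DEFAULT_KSIZE

    def __post_init__(self):
        if self.ksize % 2 == 0 or self.ksize < 3:
            raise ValueError(f"ksize must be odd and >= 3, got {self.ksize}")
        for name in ("lam", "sigma", "gamma"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        object.__setattr__(self, "theta", float(self.theta) % (2 * np.pi))


@dataclass
class GaborBank:
    """An ordered stack of fixed kernels plus their parameters."""

    kernels: list[np.ndarray]
    params: list[GaborParams]
    passthrough: bool = True

    def __post_init__(self):
        if len(self.kernels) != len(self.params):
            raise ValueError("kernels and params must have the same length")
        for k in self.kernels:
            if not np.isfinite(k).all():
                raise ValueError("non-finite kernel in bank")

    def __len__(self):
        return len(self.kernels)

    def n_output_channels(self, c_in: int) -> int:
        return c_in * len(self.kernels) + (c_in if self.passthrough else 0)

    @property
    def n_trainable_parameters(self) -> int:
        """The bank is a constant transform: always zero."""
        return 0


def make_gabor_kernel(params: GaborParams) -> np.ndarray:
    """Evaluate the kernel on its (ksize x ksize) grid.

    Entry [row, col] corresponds to offsets y = row - c, x = col - c with
    c = (ksize - 1) / 2.
    """
    c = (params.ksize - 1) // 2
    ys, xs = np.mgrid[-c:c + 1, -c:c + 1].astype(np.float64)
    ct, st = np.cos(params.theta), np.sin(params.theta)
    x_th = xs * ct + ys * st
    y_th = -xs * st + ys * ct
    envelope = np.exp(-0.5 * (x_th ** 2 + params.gamma ** 2 * y_th ** 2) / params.sigma ** 2)
    carrier = np.cos(2 * np.pi * x_th / params.lam + params.psi)
    return envelope * carrier


def build_bank(n_orientations: int = DEFAULT_N_ORIENTATIONS,
               lam: float | list[float] = DEFAULT_LAMBDA,
               sigma: float = DEFAULT_SIGMA,
               gamma: float = DEFAULT_GAMMA,
               psi: float = DEFAULT_PSI,
               ksize: int = DEFAULT_KSIZE,
               passthrough: bool = True,
               zero_mean: bool = False) -> GaborBank:
    """Build a bank with orientations theta_k = k*pi/n, k = 0..n-1.

    ``lam`` may be a list of wavelengths; the bank then holds
    n_orientations x n_frequencies kernels, orientation-major.
    ``zero_mean`` subtracts each kernel's mean (off by default: the
    analytic kernel has no normaliser).
    """
    if n_orientations < 1:
        raise ValueError(f"n_orientations must be >= 1, got {n_orientations}")
    lams = list(np.atleast_1d(lam).astype(float))
    params = [GaborParams(theta=k * np.pi / n_orientations, lam=lv, sigma=sigma,
                          gamma=gamma, psi=psi, ksize=ksize)
              for k in range(n_orientations) for lv in lams]
    kernels = [make_gabor_kernel(p) for p in params]
    if zero_mean:
        kernels = [k - k.mean() for k in kernels]
    return GaborBank(kernels=kernels, params=params, passthrough=passthrough)


def apply_bank_batch(images: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Filter a batch (B,H,W,C) -> (B,H,W,C') by depthwise cross-correlation.

    Zero 'same' padding; output channel order is input-channel major,
    kernel minor, with the untouched input channels first when
    ``bank.passthrough`` is set.
    """
    images = np.asarray(images)
    if images.ndim != 4:
        raise ValueError(f"expected a rank-4 batch, got shape {images.shape}")
    if not np.isfinite(images).all():
        raise ValueError("non-finite pixel values in input")
    b, h, w, c = images.shape
    ksize = bank.params[0].ksize
    if h < ksize or w < ksize:
        raise ValueError(f"image {h}x{w} smaller than kernel size {ksize}")
    kstack = np.stack(bank.kernels).astype(images.dtype)  # (K,k,k)
    pad = ksize // 2
    xp = np.pad(images, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (ksize, ksize), axis=(1, 2))  # (B,H,W,C,k,k)
    filtered = np.einsum("bhwcuv,kuv->bhwck", win, kstack, optimize=True)
    filtered = filtered.reshape(b, h, w, c * len(bank.kernels))
    if bank.passthrough:
        return np.concatenate([images, filtered], axis=-1)
    return filtered


def apply_bank(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Single-image convenience wrapper: (H,W,C) -> (H,W,C')."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a rank-3 image, got shape {image.shape}")
    return apply_bank_batch(image[None], bank)[0]
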