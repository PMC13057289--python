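"""Leaf Texture Attention Module (LeafTAM).

Sequential dual attention over the CNN feature map F:

1. channel attention — a squeeze-excitation style gate: the per-channel
   spatial mean z is pushed through a bias-free bottleneck MLP,
   a = sigmoid(W2 . relu(W1 . z)), and F is scaled channel-wise: F' = F (.) a;
2. spatial attention — the channel-mean map of F' is convolved with a
   single 7x7 filter and squashed, M_s = sigmoid(conv7(mean_c F')), then
   F'' = F' (.) M_s;
3. global average pooling of F'' yields the TAM feature vector.

Both gates lie strictly in (0,1), so LeafTAM can only attenuate — it
re-weights "what" (channels) and then "where" (pixels).  F'' is cached by
the full model as the Grad-CAM target layer.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor


class ChannelAttention(nn.Module):
    """Bottleneck-MLP channel gate. No bias terms in either layer."""

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        super().__init__()
        if reduction_ratio < 1:
            raise ValueError(f"reduction_ratio must be >= 1, got {reduction_ratio}")
        self.channels = channels
        self.reduction_ratio = reduction_ratio
        hidden = max(1, int(np.ceil(channels / reduction_ratio)))
        self.W1 = Tensor(nn.kaiming_uniform(rng, (channels, hidden), fan_in=channels),
                         requires_grad=True)
        self.W2 = Tensor(nn.kaiming_uniform(rng, (hidden, channels), fan_in=hidden),
                         requires_grad=True)

    def forward(self, F: Tensor) -> Tensor:
        """(B,H,W,C) -> F' = F (.) sigmoid(W2 relu(W1 z))."""
        if F.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {F.shape[-1]}")
        z = T.tmean(F, axis=(1, 2))  # (B,C)
        a = T.sigmoid(T.matmul(T.relu(T.matmul(z, self.W1)), self.W2))  # (B,C)
        return F * T.reshape(a, (F.shape[0], 1, 1, self.channels))

    __call__ = forward


class SpatialAttention(nn.Module):
    """Channel-mean -> single 7x7 conv (with bias) -> sigmoid gate map."""

    def __init__(self, rng: np.random.Generator, ksize: int = 7):
        super().__init__()
        self.conv7 = nn.Conv2d(1, 1, ksize, rng)

    def attention_map(self, Fp: Tensor) -> Tensor:
        m = T.tmean(Fp, axis=3, keepdims=True)  # (B,H,W,1)
        return T.sigmoid(self.conv7(m))

    def forward(self, Fp: Tensor) -> Tensor:
        return Fp * self.attention_map(Fp)

    __call__ = forward


class LeafTAM(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction_ratio: int = 16):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction_ratio, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, F3: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (F'', GAP(F'')). F'' is the Grad-CAM target."""
        Fpp = self.spatial(self.channel(F3))
        return Fpp, T.tmean(Fpp, axis=(1, 2))

    __call__ = forward


# ---------------------------------------------------------------------
# functional wrappers on plain arrays (single H,W,C feature maps)
# ---------------------------------------------------------------------

def channel_descriptor(F: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a single (H,W,C) map."""
    F = np.asarray(F)
    if F.ndim != 3 or F.size == 0:
        raise ValueError(f"expected a non-empty rank-3 map, got shape {F.shape}")
    return F.mean(axis=(0, 1))


def channel_attention(F: np.ndarray, ca: ChannelAttention) -> np.ndarray:
    with T.no_grad():
        out = ca(Tensor(np.asarray(F)[None]))
    return out.data[0]


def spatial_attention(Fp: np.ndarray, sa: SpatialAttention) -> np.ndarray:
    with T.no_grad():
        out = sa(Tensor(np.asarray(Fp)[None]))
    return out.data[0]


def leaftam_forward(F3: np.ndarray, tam: LeafTAM) -> tuple[np.ndarray, np.ndarray]:
    with T.no_grad():
        Fpp, feats = tam(Tensor(np.asarray(F3)[None]))
    return Fpp.data[0], feats.data[0]
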