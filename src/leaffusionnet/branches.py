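"""The two learned feature extractors.

CNN branch (local features): three conv blocks over the Gabor-enhanced
image, each ``3x3 conv -> ReLU -> 2x2 max-pool``, with filter depths
32/64/128 by default, followed by global average pooling of the final map.

ViT branch (global context): the original image resized to a square grid,
cut into non-overlapping patches, linearly embedded, and run through
pre-norm transformer encoder blocks with multi-head scaled dot-product
attention.  Trained from scratch by default; ``load_pretrained`` accepts an
external checkpoint of matching geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class FeatureMap:
    """Rank-3 (or batched rank-4) spatial feature tensor with provenance."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim not in (3, 4):
            raise ValueError(f"FeatureMap expects rank 3 or 4, got {v.ndim}")
        if not np.isfinite(v).all():
            raise ValueError("non-finite entries in feature map")
        self.values = v


@dataclass
class CnnConfig:
    widths: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3

    def __post_init__(self):
        if not self.widths or any(w <= 0 for w in self.widths):
            raise ValueError(f"widths must be positive, got {self.widths}")


@dataclass
class VitConfig:
    input_side: int = 224
    patch_size: int = 16
    d_model: int = 192
    depth: int = 6
    n_heads: int = 3
    feature_mode: str = "class_token"  # or "mean_pool"
    use_pos_embed: bool = True

    def __post_init__(self):
        if self.input_side % self.patch_size:
            raise ValueError(
                f"input_side {self.input_side} not divisible by patch_size {self.patch_size}")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}")
        if self.feature_mode not in ("class_token", "mean_pool"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")

    @property
    def n_patches(self) -> int:
        return (self.input_side // self.patch_size) ** 2


# ---------------------------------------------------------------------
# CNN branch
# ---------------------------------------------------------------------

class CnnBranch(nn.Module):
    def __init__(self, c_in: int, cfg: CnnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        blocks = nn.ModuleList()
        prev = c_in
        for w in cfg.widths:
            blocks.append(nn.Conv2d(prev, w, cfg.kernel_size, rng))
            prev = w
        self.blocks = blocks

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(B,H,W,C) -> (F3 (B,h,w,widths[-1]), GAP features (B,widths[-1]))."""
        h, w = x.shape[1], x.shape[2]
        div = 2 ** len(self.cfg.widths)
        if h % div or w % div:
            raise ValueError(
                f"spatial side {h}x{w} must be divisible by {div} "
                f"(three stride-2 pools)")
        for conv in self.blocks:
            x = T.maxpool2x2(T.relu(conv(x)))
        feats = T.tmean(x, axis=(1, 2))
        return x, feats

    __call__ = forward


def cnn_forward(x: np.ndarray, branch: CnnBranch) -> tuple[FeatureMap, np.ndarray]:
    """Functional wrapper for a single (H,W,C) image; returns numpy values."""
    with T.no_grad():
        f3, feats = branch(Tensor(np.asarray(x)[None]))
    return FeatureMap(f3.data[0], provenance="F3"), feats.data[0]


# ---------------------------------------------------------------------
# attention and the ViT branch
# ---------------------------------------------------------------------

def scaled_dot_product_attention(Q, K, V, d_k: int):
    """softmax(Q K^T / sqrt(d_k)) V with row-wise softmax.

    Accepts 2-D (tokens x dim) or stacked (.., tokens, dim) arrays/Tensors.
    """
    Q, K, V = T.as_tensor(Q), T.as_tensor(K), T.as_tensor(V)
    if Q.shape[-1] != d_k or K.shape[-1] != d_k:
        raise ValueError(
            f"Q/K last dimension must equal d_k={d_k}, got {Q.shape[-1]}/{K.shape[-1]}")
    if V.shape[-2] != K.shape[-2]:
        raise ValueError("V must have as many rows as K")
    scores = T.matmul(Q, T.transpose(K, tuple(range(K.ndim - 2)) + (K.ndim - 1, K.ndim - 2))) \
        if K.ndim > 2 else T.matmul(Q, T.transpose(K, (1, 0)))
    weights = T.softmax(scores * (1.0 / np.sqrt(d_k)), axis=-1)
    return T.matmul(weights, V)


class MultiHeadAttention(nn.Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = nn.Dense(d_model, 3 * d_model, rng)
        self.proj = nn.Dense(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x)  # (B,N,3D)
        qkv = T.reshape(qkv, (b, n, 3, self.n_heads, self.d_head))
        qkv = T.transpose(qkv, (2, 0, 3, 1, 4))  # (3,B,H,N,dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        out = scaled_dot_product_attention(q, k, v, self.d_head)  # (B,H,N,dh)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (b, n, d))
        return self.proj(out)

    __call__ = forward


class EncoderBlock(nn.Module):
    """Pre-norm transformer block with a GELU MLP (expansion 4)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = nn.LayerNorm(d_model)
        self.fc1 = nn.Dense(d_model, 4 * d_model, rng)
        self.fc2 = nn.Dense(4 * d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.fc2(T.gelu(self.fc1(self.ln2(x))))
        return x

    __call__ = forward


class VitBranch(nn.Module):
    def __init__(self, cfg: VitConfig, rng: np.random.Generator, c_in: int = 3):
        super().__init__()
        self.cfg = cfg
        p = cfg.patch_size
        self.embed = nn.Dense(p * p * c_in, cfg.d_model, rng)
        n_tokens = cfg.n_patches + (1 if cfg.feature_mode == "class_token" else 0)
        if cfg.feature_mode == "class_token":
            self.cls = Tensor(nn.trunc_normal(rng, (1, 1, cfg.d_model)), requires_grad=True)
        self.pos = Tensor(nn.trunc_normal(rng, (1, n_tokens, cfg.d_model)),
                          requires_grad=True)
        self.blocks = nn.ModuleList(
            [EncoderBlock(cfg.d_model, cfg.n_heads, rng) for _ in range(cfg.depth)])
        self.ln_out = nn.LayerNorm(cfg.d_model)

    def patchify(self, x: Tensor) -> Tensor:
        """(B,S,S,C) -> (B, n_patches, p*p*C), row-major patch order."""
        b, s1, s2, c = x.shape
        p = self.cfg.patch_size
        if s1 != s2 or s1 != self.cfg.input_side:
            raise ValueError(
                f"ViT input must be {self.cfg.input_side}x{self.cfg.input_side} "
                f"square, got {s1}x{s2}")
        g = s1 // p
        x = T.reshape(x, (b, g, p, g, p, c))
        x = T.transpose(x, (0, 1, 3, 2, 4, 5))
        return T.reshape(x, (b, g * g, p * p * c))

    def forward(self, x: Tensor) -> Tensor:
        """(B,S,S,C) -> (B, d_model)."""
        tokens = self.embed(self.patchify(x))
        b = tokens.shape[0]
        if self.cfg.feature_mode == "class_token":
            cls = T.matmul(Tensor(np.ones((b, 1, 1), dtype=tokens.dtype)), self.cls)
            tokens = T.concat([cls, tokens], axis=1)
        if self.cfg.use_pos_embed:
            tokens = tokens + self.pos
        for blk in self.blocks:
            tokens = blk(tokens)
        tokens = self.ln_out(tokens)
        if self.cfg.feature_mode == "class_token":
            return tokens[:, 0, :]
        return T.tmean(tokens, axis=1)

    __call__ = forward

    def load_pretrained(self, path: str):
        """Load externally trained weights of identical geometry (npz)."""
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})


def vit_forward(x: np.ndarray, branch: VitBranch) -> np.ndarray:
    """Functional wrapper for a single (S,S,3) image; returns numpy values."""
    with T.no_grad():
        out = branch(Tensor(np.asarray(x)[None]))
    return out.data[0]
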