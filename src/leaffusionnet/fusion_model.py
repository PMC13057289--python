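"""LeafFusionNet assembly: Gabor -> CNN -> LeafTAM stream, ViT stream,
three-way feature concatenation, and the classification head.

The fused vector Z = concat(cnn_features, vit_features, tam_features) is
passed through Dense(512)+ReLU -> BatchNorm -> Dropout ->
Dense(256)+ReLU -> BatchNorm -> Dropout -> Dense(K) -> softmax.  Training
minimises sparse categorical cross-entropy, -log p_y, computed from the
logits with a log-sum-exp stabilisation.

Ablation variants (plain CNN, CNN+ViT+LeafTAM without Gabor, full model)
are expressed through the ``use_gabor`` / ``use_vit`` / ``use_leaftam``
switches so every variant runs through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

from . import gabor_bank as gb
from . import nn
from .branches import CnnBranch, CnnConfig, VitBranch, VitConfig
from .leaftam import LeafTAM
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class HeadConfig:
    hidden: tuple[int, ...] = (512, 256)
    dropout_rate: float = 0.3
    n_classes: int = 38

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden):
            raise ValueError(f"hidden widths must be positive, got {self.hidden}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must lie in [0,1), got {self.dropout_rate}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")


@dataclass
class GaborConfig:
    n_orientations: int = 8
    lambdas: tuple[float, ...] = (4.0,)
    sigma: float = 2.0
    gamma: float = 0.5
    psi: float = 0.0
    ksize: int = 7
    passthrough: bool = True
    zero_mean: bool = False

    def build(self) -> gb.GaborBank:
        return gb.build_bank(self.n_orientations, list(self.lambdas), self.sigma,
                             self.gamma, self.psi, self.ksize, self.passthrough,
                             self.zero_mean)


@dataclass
class ModelConfig:
    image_side: int = 224
    n_classes: int = 38
    use_gabor: bool = True
    use_vit: bool = True
    use_leaftam: bool = True
    gabor: GaborConfig = field(default_factory=GaborConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    vit: VitConfig = field(default_factory=VitConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    reduction_ratio: int = 16

    def __post_init__(self):
        self.head.n_classes = self.n_classes

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            image_side=d["image_side"], n_classes=d["n_classes"],
            use_gabor=d["use_gabor"], use_vit=d["use_vit"],
            use_leaftam=d["use_leaftam"],
            gabor=GaborConfig(**{**d["gabor"],
                                 "lambdas": tuple(d["gabor"]["lambdas"])}),
            cnn=CnnConfig(widths=tuple(d["cnn"]["widths"]),
                          kernel_size=d["cnn"]["kernel_size"]),
            vit=VitConfig(**d["vit"]),
            head=HeadConfig(hidden=tuple(d["head"]["hidden"]),
                            dropout_rate=d["head"]["dropout_rate"],
                            n_classes=d["head"]["n_classes"]),
            reduction_ratio=d["reduction_ratio"],
        )


def tiny_profile(n_classes: int = 4, image_side: int = 64) -> ModelConfig:
    """Desk-scale profile: 64x64 inputs, CNN widths 8/16/32, ViT depth 2."""
    return ModelConfig(
        image_side=image_side,
        n_classes=n_classes,
        gabor=GaborConfig(lambdas=(4.0, 8.0), zero_mean=True),
        cnn=CnnConfig(widths=(8, 16, 32)),
        vit=VitConfig(input_side=image_side, patch_size=16, d_model=64,
                      depth=2, n_heads=2),
        head=HeadConfig(n_classes=n_classes),
        reduction_ratio=16,
    )


@dataclass
class FusedVector:
    """Concatenated stream features, byte-exact order (cnn, vit, tam)."""

    values: np.ndarray
    lengths: tuple[int, ...]


def fuse(cnn_features, vit_features, tam_features) -> FusedVector:
    """Concatenate the three streams (no rescaling) in fixed order."""
    parts = [np.asarray(v, dtype=float) for v in
             (cnn_features, vit_features, tam_features)]
    for name, p in zip(("cnn", "vit", "tam"), parts):
        if p.size == 0:
            raise ValueError(f"{name} feature stream is empty")
        if not np.isfinite(p).all():
            raise ValueError(f"{name} feature stream has non-finite entries")
    return FusedVector(values=np.concatenate(parts),
                       lengths=tuple(p.size for p in parts))


class ClassificationHead(nn.Module):
    def __init__(self, d_in: int, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        layers = nn.ModuleList()
        prev = d_in
        for h in cfg.hidden:
            layers.append(nn.Dense(prev, h, rng))
            layers.append(nn.BatchNorm1d(h))
            layers.append(nn.Dropout(cfg.dropout_rate))
            prev = h
        self.layers = layers
        self.out = nn.Dense(prev, cfg.n_classes, rng)

    def forward(self, z: Tensor) -> Tensor:
        """Returns logits (softmax is applied by the caller)."""
        x = z
        for layer in self.layers:
            if isinstance(layer, nn.Dense):
                x = T.relu(layer(x))
            else:
                x = layer(x)
        return self.out(x)

    __call__ = forward


def head_forward(z: np.ndarray, head: ClassificationHead, training: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Probability output of the head for a single fused vector or batch."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    z = np.atleast_2d(z)
    head.train(training)
    if rng is not None:
        for m in head.modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng
    with T.no_grad() if not training else _nullcontext():
        probs = T.softmax(head(Tensor(z)), axis=-1)
    head.eval()
    return probs.data[0] if single else probs.data


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *a):
        return False


def sparse_ce_loss(probs, y) -> float:
    """-log(probs[y]); mean over the batch when batched.

    ``probs`` is a probability vector (K,) with integer ``y``, or a batch
    (B,K) with ``y`` of shape (B,).  For training from logits use
    ``nn.tensor.cross_entropy_with_logits`` which goes through log-sum-exp.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim == 1:
        p, y = p[None], np.asarray([y])
    else:
        y = np.asarray(y)
    k = p.shape[1]
    if np.any((y < 0) | (y >= k)):
        raise ValueError(f"class index out of range [0, {k})")
    return float(-np.log(p[np.arange(len(y)), y]).mean())


class ForwardOutput:
    """Probabilities plus cached activations for Grad-CAM."""

    def __init__(self, probs: Tensor, logits: Tensor, cache: dict):
        self.probs = probs
        self.logits = logits
        self.cache = cache


class LeafFusionNet(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2025]))
        self.bank = cfg.gabor.build() if cfg.use_gabor else None
        c_in = self.bank.n_output_channels(3) if self.bank is not None else 3
        self.cnn = CnnBranch(c_in, cfg.cnn, rng)
        c_f3 = cfg.cnn.widths[-1]
        if cfg.use_leaftam:
            self.tam = LeafTAM(c_f3, rng, cfg.reduction_ratio)
        if cfg.use_vit:
            self.vit = VitBranch(cfg.vit, rng)
        d_fused = c_f3 \
            + (cfg.vit.d_model if cfg.use_vit else 0) \
            + (c_f3 if cfg.use_leaftam else 0)
        self.head = ClassificationHead(d_fused, cfg.head, rng)

    # -- preprocessing stages that carry no gradient -------------------
    def _gabor_stage(self, images: np.ndarray) -> np.ndarray:
        if self.bank is None:
            return images
        return gb.apply_bank_batch(images, self.bank)

    def _vit_stage_input(self, images: np.ndarray) -> np.ndarray:
        side = self.cfg.vit.input_side
        if images.shape[1] == side and images.shape[2] == side:
            return images
        out = np.empty((images.shape[0], side, side, images.shape[3]),
                       dtype=images.dtype)
        for i, im in enumerate(images):
            out[i] = _sk_resize(im, (side, side), order=1, anti_aliasing=False,
                                preserve_range=True)
        return out

    def forward(self, images: np.ndarray, training: bool = False) -> ForwardOutput:
        """images: (B,H,W,3) float in [0,1], already preprocessed/augmented."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError(f"expected (B,H,W,3) images, got {images.shape}")
        self.train(training)
        streams = []
        cache: dict = {}
        x = Tensor(self._gabor_stage(images))
        f3, cnn_feat = self.cnn(x)
        cache["F3"] = f3
        streams.append(cnn_feat)
        if self.cfg.use_vit:
            vit_feat = self.vit(Tensor(self._vit_stage_input(images)))
            streams.append(vit_feat)
        if self.cfg.use_leaftam:
            fpp, tam_feat = self.tam(f3)
            cache["Fpp"] = fpp
            streams.append(tam_feat)
        z = T.concat(streams, axis=-1) if len(streams) > 1 else streams[0]
        cache["fused"] = z
        logits = self.head(z)
        probs = T.softmax(logits, axis=-1)
        return ForwardOutput(probs, logits, cache)

    __call__ = forward

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode class probabilities, graph-free."""
        outs = []
        with T.no_grad():
            for i in range(0, len(images), batch_size):
                outs.append(self(images[i:i + batch_size], training=False).probs.data)
        return np.concatenate(outs, axis=0)


def model_forward(model: LeafFusionNet, image: np.ndarray,
                  training: bool = False) -> tuple[np.ndarray, dict]:
    """Single-image convenience: returns (probs (K,), cache)."""
    out = model(np.asarray(image)[None], training=training)
    return out.probs.data[0], out.cache


def count_parameters(model: LeafFusionNet) -> dict[str, int]:
    """Trainable parameter count per component; the Gabor bank is always 0."""
    counts = {"gabor": 0}
    for name in ("cnn", "vit", "tam", "head"):
        if name in model._modules:
            counts[name] = model._modules[name].n_parameters()
    counts["total"] = model.n_parameters()
    return counts
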