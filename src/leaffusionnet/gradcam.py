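"""Grad-CAM on the LeafTAM output feature map F''.

Standard construction: differentiate the pre-softmax score of the target
class with respect to the cached feature map, average the gradient over
space to get per-channel weights alpha_c, form ReLU(sum_c alpha_c F''_c),
min-max normalise (a constant raw map normalises to all zeros by
convention) and bilinearly upsample to input resolution.  Pre-softmax
logits are used rather than probabilities so confident predictions do not
shrink the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as sk_resize

from .fusion_model import LeafFusionNet


@dataclass
class Heatmap:
    values: np.ndarray          # feature-map resolution, normalized to [0,1]
    upsampled: np.ndarray       # input resolution
    target_class: int
    normalized: bool = True


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def grad_cam(model: LeafFusionNet, image: np.ndarray,
             target_class: int | None = None, layer: str = "Fpp") -> Heatmap:
    """Class-discriminative heatmap for one (H,W,3) image.

    ``layer`` selects the target feature map: "Fpp" (the LeafTAM output,
    default) or "F3" (the raw CNN map).
    """
    image = np.asarray(image)
    out = model(image[None], training=False)
    if target_class is None:
        target_class = int(out.probs.data[0].argmax())
    if not 0 <= target_class < model.cfg.n_classes:
        raise ValueError(f"target_class {target_class} out of range")
    if layer not in out.cache:
        raise KeyError(
            f"layer {layer!r} not cached; run model_forward with the "
            f"corresponding module enabled (available: {sorted(out.cache)})")
    fmap = out.cache[layer]
    model.zero_grad()
    seed = np.zeros_like(out.logits.data)
    seed[0, target_class] = 1.0
    out.logits.backward(seed)
    if fmap.grad is None:
        raise RuntimeError("no gradient reached the target layer")
    grad = fmap.grad[0]            # (h,w,C)
    act = fmap.data[0]
    alpha = grad.mean(axis=(0, 1))  # gradient-GAP channel weights
    raw = np.maximum((act * alpha).sum(axis=-1), 0.0)
    values = _normalize(raw)
    upsampled = sk_resize(values, image.shape[:2], order=1, anti_aliasing=False,
                          mode="edge")
    return Heatmap(values=values, upsampled=upsampled,
                   target_class=target_class, normalized=True)


def overlay(image: np.ndarray, heatmap: Heatmap, colormap: str = "jet",
            alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a jet-style rendering of the heatmap over the image.

    Returns a uint8 RGB array of the input's size (red/yellow = strong
    attention).
    """
    image = np.asarray(image, dtype=float)
    hm = heatmap.upsampled
    if hm.shape != image.shape[:2]:
        raise ValueError(
            f"heatmap size {hm.shape} does not match image {image.shape[:2]}")
    cmap = colormaps[colormap]
    colored = cmap(hm)[..., :3]
    blended = (1 - alpha) * image + alpha * colored
    return np.round(np.clip(blended, 0, 1) * 255).astype(np.uint8)


def localization_score(heatmap: Heatmap, lesion_mask: np.ndarray) -> float:
    """Mean normalized heat inside the lesion mask minus mean outside."""
    m = np.asarray(lesion_mask, dtype=bool)
    if m.shape != heatmap.upsampled.shape:
        raise ValueError("mask and heatmap sizes differ")
    if not m.any() or m.all():
        raise ValueError("mask must be a proper subset of the image")
    return float(heatmap.upsampled[m].mean() - heatmap.upsampled[~m].mean())
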