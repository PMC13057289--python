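"""YAML configuration loading.

Config files use dotted sections mirroring the module structure, e.g.::

    data:
      root: data/images
      seed: 0
    gabor:
      n_orientations: 8
      lambdas: [4.0]
    cnn:
      widths: [32, 64, 128]
    vit:
      input_side: 224
      patch_size: 16
      d_model: 192
      depth: 6
      n_heads: 3
    head:
      hidden: [512, 256]
      dropout_rate: 0.3
    model:
      n_classes: 38
      image_side: 224
    train:
      lr: 1.0e-4
      batch_size: 16
      max_epochs: 50
      early_stop_patience: 5
      seed: 0

Unspecified keys fall back to the defaults of the corresponding dataclass.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .branches import CnnConfig, VitConfig
from .fusion_model import GaborConfig, HeadConfig, ModelConfig
from .train_eval import TrainConfig


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _build(cls, section: dict, tuple_fields=()):
    kw = dict(section or {})
    for f in tuple_fields:
        if f in kw:
            kw[f] = tuple(kw[f])
    return cls(**kw)


def model_config_from_dict(d: dict) -> ModelConfig:
    model = dict(d.get("model") or {})
    return ModelConfig(
        image_side=model.get("image_side", 224),
        n_classes=model.get("n_classes", 38),
        use_gabor=model.get("use_gabor", True),
        use_vit=model.get("use_vit", True),
        use_leaftam=model.get("use_leaftam", True),
        reduction_ratio=(d.get("leaftam") or {}).get("reduction_ratio", 16),
        gabor=_build(GaborConfig, d.get("gabor"), tuple_fields=("lambdas",)),
        cnn=_build(CnnConfig, d.get("cnn"), tuple_fields=("widths",)),
        vit=_build(VitConfig, d.get("vit")),
        head=_build(HeadConfig, d.get("head"), tuple_fields=("hidden",)),
    )


def train_config_from_dict(d: dict) -> TrainConfig:
    return _build(TrainConfig, d.get("train"))
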