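"""Dataset indexing, stratified splitting and preprocessing/augmentation.

The expected on-disk layout is class-per-folder (the PlantVillage
convention): ``root/<class_name>/<image>.png|jpg``.  Class ids are assigned
by sorted folder name.  Splitting is two-stage stratified sampling —
per class, 20% to test, then 20% of the remainder to validation — giving
overall fractions close to 64/16/20.

Preprocessing: decode -> scale to [0,1] -> bilinear resize to a square.
Augmentation (training only, applied before Gabor filtering and the ViT
resize): horizontal flip with p = 0.5, rotation uniform in +-10% of a full
turn (+-36 degrees), and centre zoom uniform in [0.9, 1.1], bilinear with
reflection fill.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import AffineTransform, resize as sk_resize, warp

log = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class DatasetIndex:
    records: list[tuple[Path, str, int]]
    class_names: list[str]
    n_skipped: int = 0

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([cid for _, _, cid in self.records], dtype=np.int64)


@dataclass
class SplitSpec:
    train: list[int]
    val: list[int]
    test: list[int]
    seed: int

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split leakage: partitions overlap")

    def as_dict(self) -> dict[str, list[int]]:
        return {"train": self.train, "val": self.val, "test": self.test}


def index_dataset(root: str | Path) -> DatasetIndex:
    """Enumerate a class-per-folder tree deterministically.

    Unreadable files are skipped with a logged count; an empty root or a
    single class is rejected.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.is_dir() else []
    class_dirs = [d for d in class_dirs
                  if any(f.suffix.lower() in IMAGE_EXTENSIONS for f in d.iterdir())]
    if len(class_dirs) < 2:
        raise ValueError(
            f"dataset root {root} must contain at least two class folders with images")
    class_names = [d.name for d in class_dirs]
    records: list[tuple[Path, str, int]] = []
    skipped = 0
    for cid, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError):
                skipped += 1
                log.warning("skipping unreadable image %s", f)
                continue
            records.append((f, d.name, cid))
    if skipped:
        log.info("index_dataset: skipped %d unreadable file(s)", skipped)
    return DatasetIndex(records=records, class_names=class_names, n_skipped=skipped)


def _round_half_even(x: float) -> int:
    return int(round(x))


def stratified_split(index: DatasetIndex, test_frac: float = 0.2,
                     val_frac_of_remainder: float = 0.2, seed: int = 0) -> SplitSpec:
    """Two-stage per-class stratified split (train/val/test ~ 64/16/20).

    Per class: round(n * test_frac) samples to test, then
    round(remainder * val_frac) to validation, remainder to train;
    each split is guaranteed non-empty per class (requires n >= 3).
    """
    return stratified_split_labels(index.labels, index.class_names,
                                   test_frac, val_frac_of_remainder, seed)


def stratified_split_labels(labels: np.ndarray, class_names: list[str],
                            test_frac: float = 0.2,
                            val_frac_of_remainder: float = 0.2,
                            seed: int = 0) -> SplitSpec:
    """Label-array form of :func:`stratified_split` (for in-memory data)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cid, name in enumerate(class_names):
        idx = np.flatnonzero(labels == cid)
        if len(idx) < 3:
            raise ValueError(
                f"class {name!r} has only {len(idx)} sample(s); need >= 3 to split")
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_test = min(max(_round_half_even(n * test_frac), 1), n - 2)
        rem = n - n_test
        n_val = min(max(_round_half_even(rem * val_frac_of_remainder), 1), rem - 1)
        test.extend(idx[:n_test].tolist())
        val.extend(idx[n_test:n_test + n_val].tolist())
        train.extend(idx[n_test + n_val:].tolist())
    return SplitSpec(train=sorted(train), val=sorted(val), test=sorted(test), seed=seed)


def write_split_manifest(index: DatasetIndex, split: SplitSpec, path: str | Path):
    """CSV manifest (path, class_name, class_id, split) for reproducibility."""
    member = {}
    for name, ids in split.as_dict().items():
        for i in ids:
            member[i] = name
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class_name", "class_id", "split"])
        for i, (p, cname, cid) in enumerate(index.records):
            w.writerow([str(p), cname, cid, member.get(i, "")])


# ---------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------

def resize_bilinear(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to (side, side), pixel-centre aligned."""
    return sk_resize(image, (side, side), order=1, anti_aliasing=False,
                     preserve_range=True, mode="edge")


def preprocess(path_or_array, side: int = 224) -> np.ndarray:
    """Decode an RGB image file -> float (side, side, 3) array in [0,1]."""
    if isinstance(path_or_array, (str, Path)):
        try:
            with Image.open(path_or_array) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64)
        except (UnidentifiedImageError, OSError) as e:
            raise ValueError(f"cannot decode image file {path_or_array}: {e}") from e
    else:
        arr = np.asarray(path_or_array, dtype=np.float64)
    arr = arr / 255.0
    if arr.shape[:2] != (side, side):
        arr = resize_bilinear(arr, side)
    return np.clip(arr, 0.0, 1.0)


def augment(image: np.ndarray, rng: np.random.Generator,
            max_rotation_deg: float = 36.0, max_zoom: float = 0.1,
            p_flip: float = 0.5, *, flip: bool | None = None,
            angle_deg: float | None = None, zoom: float | None = None) -> np.ndarray:
    """Random flip / rotation / zoom with reflection fill.

    The keyword-only arguments force a specific transform (used in tests);
    when left as ``None`` they are drawn from ``rng``.
    """
    image = np.asarray(image, dtype=np.float64)
    if flip is None:
        flip = bool(rng.random() < p_flip)
    if angle_deg is None:
        angle_deg = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    if zoom is None:
        zoom = float(rng.uniform(1.0 - max_zoom, 1.0 + max_zoom))
    out = image
    if flip:
        out = out[:, ::-1]
    if angle_deg != 0.0 or zoom != 1.0:
        h, w = out.shape[:2]
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        ang = np.deg2rad(angle_deg)
        # forward map about the image centre: rotate by ang, magnify by zoom
        tf = (AffineTransform(translation=-centre)
              + AffineTransform(rotation=ang, scale=zoom)
              + AffineTransform(translation=centre))
        out = warp(out, tf.inverse, order=1, mode="reflect", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def load_split_arrays(index: DatasetIndex, split: SplitSpec, side: int,
                      dtype=np.float32) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Materialise each split as (images, labels) arrays."""
    labels = index.labels
    out = {}
    for name, ids in split.as_dict().items():
        X = np.stack([preprocess(index.records[i][0], side) for i in ids]).astype(dtype)
        out[name] = (X, labels[ids])
    return out
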