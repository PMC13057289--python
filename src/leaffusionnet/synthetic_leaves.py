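"""Procedural generator of labelled leaf-like texture images.

Each image shows a green elliptical "leaf" with darker venation on a brown
background.  Disease classes differ by the orientation/frequency statistics
of the texture painted inside the leaf — precisely the structure the Gabor
and attention pathway is built to exploit:

* ``healthy`` — venation only, no lesion;
* ``spots``   — dark circular lesions (radius ~2.5-4.5 px at side 64);
* ``streaks`` — oriented sinusoidal dark bands at a seeded angle near a
  class-canonical orientation;
* ``mottle``  — low-frequency blotchy discolouration from a coarse
  multiplicative noise field.

The exact lesion mask is returned (and written) alongside every image, so
attention-localisation claims can be quantified — something real leaf
photographs do not offer.  Every image is a pure function of
``(dataset seed, class, index)``; additive sensor-style noise with standard
deviation ``noise_level`` (default 0.08 in [0,1] pixel units) controls
difficulty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .gabor_bank import apply_bank_batch, build_bank

CLASS_NAMES = ("healthy", "mottle", "spots", "streaks")  # sorted folder order
DEFAULT_NOISE_LEVEL = 0.08
STREAK_WAVELENGTH = 8.0  # pixels per cycle at image side 64
STREAK_BASE_ANGLE_DEG = 30.0
LESION_RGB = np.array([0.20, 0.15, 0.06])  # shared necrotic-tissue colour
LESION_BLEND = 0.6
LESION_AREA_FRACTION = 0.14  # of the leaf blade, for every diseased class


@dataclass
class LeafSpec:
    """Generation parameters for one image; the mask is filled in on draw."""

    class_name: str
    image_side: int = 64
    seed: int = 0
    noise_level: float = DEFAULT_NOISE_LEVEL
    lesion_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}")
        if self.image_side < 32:
            raise ValueError(f"image_side must be >= 32, got {self.image_side}")


def _smooth_field(rng: np.random.Generator, side: int, coarse: int) -> np.ndarray:
    """Low-frequency random field: coarse normal grid, bilinearly upsampled."""
    from skimage.transform import resize
    g = rng.normal(size=(coarse, coarse))
    return resize(g, (side, side), order=1, anti_aliasing=False, mode="edge")


def generate_leaf(spec: LeafSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw one leaf image. Returns (image (s,s,3) in [0,1], boolean mask)."""
    s = spec.image_side
    scale = s / 64.0
    seed = spec.seed if isinstance(spec.seed, np.random.SeedSequence) \
        else np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # leaf ellipse in a rotated frame
    cx, cy = s / 2 + rng.uniform(-2, 2, 2) * scale
    phi = rng.uniform(-0.4, 0.4)
    a = s * 0.40 * rng.uniform(0.92, 1.05)
    b = s * 0.27 * rng.uniform(0.92, 1.05)
    u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    leaf = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    # background: brown with a gentle illumination gradient
    img = np.empty((s, s, 3))
    grad = _smooth_field(rng, s, 4) * 0.04
    for c, base in enumerate((0.36, 0.26, 0.15)):
        img[..., c] = base + grad

    # leaf blade: green with smooth chlorophyll variation
    blade = np.empty((s, s, 3))
    vari = _smooth_field(rng, s, 6) * 0.035
    for c, base in enumerate((0.18, 0.50, 0.20)):
        blade[..., c] = base + vari
    # venation: midrib along the major axis plus lateral veins at +-60 deg
    vein = np.abs(v) < 0.8 * scale
    pitch = 12.0 * scale
    for sign in (+1.0, -1.0):
        w = u * 0.5 + sign * v * (np.sqrt(3) / 2)  # coordinate across 60-deg veins
        vein |= np.abs((w % pitch) - pitch / 2) < 0.5 * scale
    blade[vein & leaf] *= 0.90
    img[leaf] = blade[leaf]

    # Class-specific lesion texture.  All diseased classes share the same
    # lesion colour, blend weight and (approximately) the same lesion area
    # fraction of the blade: classes are separated by the spatial
    # *arrangement* of necrotic tissue (isotropic mid-frequency discs vs
    # oriented bands vs low-frequency blotches), not by colour or amount —
    # the discriminative signal lives in orientation/frequency statistics.
    mask = np.zeros((s, s), dtype=bool)
    leaf_area = int(leaf.sum())
    target_area = LESION_AREA_FRACTION * leaf_area
    if spec.class_name == "spots":
        for _ in range(30):
            if mask.sum() >= target_area:
                break
            r_frac, ang = np.sqrt(rng.uniform(0, 0.8)), rng.uniform(0, 2 * np.pi)
            pu, pv = r_frac * a * np.cos(ang), r_frac * b * np.sin(ang)
            px = cx + pu * np.cos(phi) - pv * np.sin(phi)
            py = cy + pu * np.sin(phi) + pv * np.cos(phi)
            radius = rng.uniform(2.5, 4.5) * scale
            mask |= ((xx - px) ** 2 + (yy - py) ** 2 <= radius ** 2) & leaf
    elif spec.class_name == "streaks":
        theta = np.deg2rad(STREAK_BASE_ANGLE_DEG + rng.uniform(-10, 10))
        lam = STREAK_WAVELENGTH * scale
        carrier = np.cos(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / lam)
        # streaks confined to a random elliptical patch of the blade;
        # the carrier threshold sets the band fill so the lesion area
        # matches the other diseased classes
        pc_u = rng.uniform(-0.25, 0.25) * a
        pc_v = rng.uniform(-0.25, 0.25) * b
        patch = (((u - pc_u) / (0.80 * a)) ** 2
                 + ((v - pc_v) / (0.80 * b)) ** 2) <= 1.0
        region = patch & leaf
        frac = min(0.95, target_area / max(int(region.sum()), 1))
        mask = region & (carrier > np.cos(np.pi * frac))
    elif spec.class_name == "mottle":
        field = _smooth_field(rng, s, max(3, s // 16))
        q = min(0.95, target_area / leaf_area)
        mask = (field < np.quantile(field[leaf], q)) & leaf
    if spec.class_name != "healthy":
        img[mask] = (1 - LESION_BLEND) * img[mask] + LESION_BLEND * LESION_RGB

    # sensor noise and illumination jitter
    img *= 1.0 + rng.uniform(-0.08, 0.08)
    img += rng.normal(0.0, spec.noise_level, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    spec.lesion_mask = mask
    return img, mask


def _image_seed(dataset_seed: int, class_index: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(dataset_seed), int(class_index), int(index)])


def generate_arrays(n_per_class: int, image_side: int = 64, seed: int = 0,
                    classes: tuple[str, ...] = CLASS_NAMES,
                    noise_level: float = DEFAULT_NOISE_LEVEL,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-memory dataset: (images (N,s,s,3) float32, labels (N,), masks (N,s,s)).

    Class ids follow the sorted class-name order, matching ``index_dataset``
    on a tree written by ``generate_dataset`` with the same seed.
    """
    classes = tuple(sorted(classes))
    X, y, masks = [], [], []
    for cid, cname in enumerate(classes):
        for i in range(n_per_class):
            spec = LeafSpec(cname, image_side, seed=_image_seed(seed, cid, i),
                            noise_level=noise_level)
            img, m = generate_leaf(spec)
            X.append(img.astype(np.float32))
            y.append(cid)
            masks.append(m)
    return np.stack(X), np.array(y, dtype=np.int64), np.stack(masks)


def generate_dataset(root: str | Path, n_per_class: int, image_side: int = 64,
                     seed: int = 0, classes: tuple[str, ...] = CLASS_NAMES,
                     noise_level: float = DEFAULT_NOISE_LEVEL,
                     force: bool = False) -> Path:
    """Write a class-per-folder PNG tree plus masks and a manifest.

    Layout: ``root/images/<class>/img_NNNN.png``,
    ``root/masks/<class>/img_NNNN.png``, ``root/manifest.csv``.
    Returns the image tree root (``root/images``).
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(
            f"{root} exists and is not empty; pass force=True to overwrite")
    classes = tuple(sorted(classes))
    img_root = root / "images"
    mask_root = root / "masks"
    rows = []
    for cid, cname in enumerate(classes):
        (img_root / cname).mkdir(parents=True, exist_ok=True)
        (mask_root / cname).mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            ss = _image_seed(seed, cid, i)
            spec = LeafSpec(cname, image_side, seed=ss, noise_level=noise_level)
            img, mask = generate_leaf(spec)
            ipath = img_root / cname / f"img_{i:04d}.png"
            mpath = mask_root / cname / f"img_{i:04d}.png"
            Image.fromarray(np.round(img * 255).astype(np.uint8)).save(ipath)
            Image.fromarray((mask * 255).astype(np.uint8)).save(mpath)
            rows.append([str(ipath), cname, str(ss.entropy), str(mpath)])
    with open(root / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class", "seed", "mask_path"])
        w.writerows(rows)
    return img_root


def gabor_energy_features(images: np.ndarray, lam: float = STREAK_WAVELENGTH,
                          n_orientations: int = 8) -> np.ndarray:
    """Per-image mean absolute Gabor response at each orientation.

    Computed on the channel-mean (grey) image with a passthrough-free,
    zero-mean bank whose envelope is matched to the wavelength
    (sigma = lam/2, so the kernels are genuinely orientation-selective);
    used to verify that the generated classes are separable by the texture
    pathway (a linear classifier on these features is the learnability
    oracle).
    """
    images = np.asarray(images)
    grey = images.mean(axis=-1, keepdims=True)
    sigma = lam / 2.0
    ksize = int(2 * np.ceil(2 * sigma) + 1)
    bank = build_bank(n_orientations=n_orientations, lam=lam, sigma=sigma,
                      ksize=ksize, passthrough=False, zero_mean=True)
    resp = apply_bank_batch(grey, bank)  # (N,H,W,n_orientations)
    return np.abs(resp).mean(axis=(1, 2))
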