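"""Dataset handling: folder ingestion, augmentation, splitting, and a
deterministic synthetic leaf-disease image generator.

The generator renders a leaf-like green ellipse on a soil-toned background
and stamps class-specific lesion motifs (spots, stripes, or rings with a
per-class color and size regime).  It exists so every other module can be
exercised end-to-end without downloading a real leaf-disease corpus; the
classes are separable by color and shape statistics by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["LabeledImageSet", "AugmentConfig", "SyntheticSpec",
           "load_image_folder", "augment_image", "split_dataset",
           "generate_synthetic_dataset", "save_image_folder"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class LabeledImageSet:
    """(image, label) pairs plus the label vocabulary.

    Images are channel-first float arrays in [0, 1] with 3 channels.
    """

    items: list            # list of (np.ndarray (3,H,W), int)
    label_names: list      # ordered vocabulary; labels index into it

    def __len__(self) -> int:
        return len(self.items)

    @property
    def num_classes(self) -> int:
        return len(self.label_names)

    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=np.int64)

    def images(self) -> np.ndarray:
        return np.stack([img for img, _ in self.items])

    def subset(self, indices) -> "LabeledImageSet":
        return LabeledImageSet([self.items[i] for i in indices], list(self.label_names))


@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_deg: float = 35.0
    noise_sigma: float = 0.01   # fraction of the [0,1] dynamic range

    def __post_init__(self):
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.max_rotation_deg < 0 or self.noise_sigma < 0:
            raise ValueError("max_rotation_deg and noise_sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    num_classes: int = 4
    per_class: int = 16
    image_size: int = 64
    seed: int = 0
    min_lesions: int = 5
    max_lesions: int = 9
    min_radius_frac: float = 0.06   # lesion radius as a fraction of image size
    max_radius_frac: float = 0.14

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if self.image_size * self.min_radius_frac < 1:
            raise ValueError(f"image_size {self.image_size} too small for the motif radii")


def load_image_folder(path: str, image_size: int | None = None) -> LabeledImageSet:
    """Read a class-per-subdirectory tree of PNG/JPEG images.

    The vocabulary is the lexicographically sorted list of subdirectory
    names, so re-loading the same folder is fully reproducible.
    """
    classes = sorted(d for d in os.listdir(path)
                     if os.path.isdir(os.path.join(path, d)))
    if not classes:
        raise ValueError(f"no class subdirectories found under {path}")
    items = []
    for label, cls in enumerate(classes):
        cdir = os.path.join(path, cls)
        files = sorted(f for f in os.listdir(cdir)
                       if f.lower().endswith(IMAGE_EXTENSIONS))
        if not files:
            raise ValueError(f"class directory {cdir} contains no images")
        for fname in files:
            fpath = os.path.join(cdir, fname)
            try:
                with Image.open(fpath) as im:
                    im = im.convert("RGB")
                    if image_size is not None:
                        im = im.resize((image_size, image_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float64) / 255.0
            except Exception as exc:
                raise ValueError(f"unreadable image file: {fpath}") from exc
            items.append((arr.transpose(2, 0, 1), label))
    return LabeledImageSet(items, classes)


def save_image_folder(dataset: LabeledImageSet, out_dir: str) -> None:
    """Write a LabeledImageSet back out as a class-per-subdirectory PNG tree."""
    counters = {}
    for img, label in dataset.items:
        cls = dataset.label_names[label]
        cdir = os.path.join(out_dir, cls)
        os.makedirs(cdir, exist_ok=True)
        k = counters.get(label, 0)
        counters[label] = k + 1
        arr = np.clip(img.transpose(1, 2, 0) * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(cdir, f"{cls}_{k:04d}.png"))


def augment_image(image: np.ndarray, config: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips, a uniform rotation in
    [0, max_rotation_deg], and additive Gaussian noise clipped to [0, 1].

    The image is channel-first in [0, 1]; the output has the same shape and
    range, and is fully determined by the generator's state.
    """
    if image.min() < 0 or image.max() > 1:
        raise ValueError("augment_image expects pixel values in [0, 1]")
    out = image
    if rng.random() < config.p_hflip:
        out = out[:, :, ::-1]
    if rng.random() < config.p_vflip:
        out = out[:, ::-1, :]
    angle = rng.uniform(0.0, config.max_rotation_deg)
    if angle != 0.0:
        # bilinear interpolation, edge-value fill, shape preserved
        out = ndimage.rotate(out, angle, axes=(1, 2), reshape=False,
                             order=1, mode="nearest")
    if config.noise_sigma > 0:
        out = out + rng.normal(0.0, config.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def split_dataset(dataset: LabeledImageSet, ratios: tuple = (6, 2, 2),
                  seed: int = 0) -> tuple:
    """Stratified train/validation/test split.

    Per class: a seeded shuffle, then floor(n * r_val / total) samples to
    validation, the same rule for test, and the remainder to train.  The
    three partitions are disjoint and exhaustive.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    total = float(sum(ratios))
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    train_idx, val_idx, test_idx = [], [], []
    for cls in range(dataset.num_classes):
        idx = np.flatnonzero(labels == cls)
        if len(idx) and len(idx) < 3:
            raise ValueError(
                f"class {dataset.label_names[cls]!r} has only {len(idx)} members; "
                "need >= 3 to stratify into train/val/test")
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(np.floor(n * ratios[1] / total))
        n_test = int(np.floor(n * ratios[2] / total))
        val_idx.extend(idx[:n_val])
        test_idx.extend(idx[n_val:n_val + n_test])
        train_idx.extend(idx[n_val + n_test:])
    return (dataset.subset(sorted(train_idx)),
            dataset.subset(sorted(val_idx)),
            dataset.subset(sorted(test_idx)))


# ---------------------------------------------------------------------- #
#  Synthetic generator
# ---------------------------------------------------------------------- #
# distinct lesion colors per class, RGB in [0,1]
_PALETTE = np.array([
    [0.55, 0.27, 0.07],   # brown necrotic spot
    [0.95, 0.85, 0.25],   # chlorotic yellow
    [0.80, 0.80, 0.82],   # powdery grey-white
    [0.45, 0.05, 0.10],   # dark rust red
    [0.95, 0.45, 0.10],   # orange rust
    [0.15, 0.10, 0.30],   # purple-black mold
    [0.90, 0.90, 0.60],   # pale blight
    [0.30, 0.20, 0.05],   # dark brown canker
])

_MOTIFS = ("spots", "stripes", "rings")


def _leaf_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Soil-toned canvas with a green leaf ellipse (seeded color jitter)."""
    yy, xx = np.mgrid[0:size, 0:size]
    soil = np.array([0.35, 0.25, 0.15]) + rng.uniform(-0.04, 0.04, 3)
    img = np.empty((3, size, size))
    img[:] = soil[:, None, None]
    cy, cx = size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2)
    ry, rx = size * rng.uniform(0.36, 0.44), size * rng.uniform(0.30, 0.38)
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    green = np.array([0.15, 0.55, 0.20]) + rng.uniform(-0.05, 0.05, 3)
    shading = 1.0 - 0.25 * ((yy - cy) / ry) ** 2
    for c in range(3):
        img[c][mask] = (green[c] * shading)[mask]
    return np.clip(img, 0, 1), mask


def _stamp_disk(img, cy, cx, r, color, ring=False):
    size = img.shape[1]
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sel = (d2 <= r * r) if not ring else ((d2 <= r * r) & (d2 >= (0.55 * r) ** 2))
    for c in range(3):
        img[c][sel] = color[c]


def _stamp_stripe(img, cy, cx, r, color, angle):
    size = img.shape[1]
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    sel = (np.abs(v) <= max(r * 0.35, 1.0)) & (np.abs(u) <= 3.0 * r)
    for c in range(3):
        img[c][sel] = color[c]


def generate_synthetic_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Render a balanced, byte-deterministic multi-class lesion image set.

    Class k fixes a motif kind (spots/stripes/rings cycling with k), a lesion
    color from the palette, and a size/count regime; each image draws its own
    lesion positions, counts and radii from a seeded stream.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    items = []
    label_names = [f"class_{k:02d}" for k in range(spec.num_classes)]
    for k in range(spec.num_classes):
        motif = _MOTIFS[k % len(_MOTIFS)]
        color = _PALETTE[k % len(_PALETTE)]
        for _ in range(spec.per_class):
            img, leaf_mask = _leaf_background(size, rng)
            n_lesions = rng.integers(spec.min_lesions, spec.max_lesions + 1)
            ys, xs = np.nonzero(leaf_mask)
            for _ in range(n_lesions):
                j = rng.integers(len(ys))
                cy, cx = ys[j], xs[j]
                r = rng.uniform(spec.min_radius_frac, spec.max_radius_frac) * size
                if motif == "spots":
                    _stamp_disk(img, cy, cx, r, color)
                elif motif == "rings":
                    _stamp_disk(img, cy, cx, r * 1.3, color, ring=True)
                else:
                    _stamp_stripe(img, cy, cx, r, color, rng.uniform(0, np.pi))
            items.append((np.clip(img, 0, 1), k))
    return LabeledImageSet(items, label_names)
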