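"""Dataset handling: synthetic OCT rendering, folder loading, preprocessing.

Real retinal OCT collections (OCT2017, OCT-C8) ship as class-per-subfolder
PNG/JPEG trees.  :func:`load_image_folder` reads that layout;
:func:`generate_synthetic_dataset` writes one, rendering seeded grayscale
cross-sections that emulate the gross morphology of the disease classes: a
stack of smooth intensity bands (the retinal layers) over a dark background,
with class-conditional lesions —

* CNV / AMD:   a bright dome bulging the outer bands upward (neovascular
               membrane / pigment-epithelium detachment),
* DME:         several dark intraretinal fluid pockets,
* CSR:         one wide dark fluid cavity under the outer band,
* DRUSEN:      small bright bumps rippling the outer band,
* DR:          scattered small dark spots (haemorrhages/exudate shadows),
* MH:          a central notch cut into the inner bands (macular hole),
* NORMAL:      clean layers —

plus multiplicative speckle noise.  Rendering is fully deterministic for a
fixed spec: the same seed yields byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .losses import normalize_class_weights

__all__ = [
    "CLASSES_4", "CLASSES_8", "SyntheticSpec", "AugmentationPolicy",
    "DatasetManifest", "generate_synthetic_dataset", "load_image_folder",
    "preprocess", "augment", "class_weights",
]

CLASSES_4 = ("CNV", "DME", "DRUSEN", "NORMAL")
CLASSES_8 = ("AMD", "CNV", "CSR", "DME", "DR", "DRUSEN", "MH", "NORMAL")

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class SyntheticSpec:
    """What to render.  Defaults give the 4-class set used throughout the
    tests: 100 training, 8 validation and 40 test images per class at
    256×256 (pre-resize, so the resize path is always exercised)."""

    classes: tuple[str, ...] = CLASSES_4
    images_per_class: dict = field(
        default_factory=lambda: {"train": 100, "val": 8, "test": 40})
    image_size: int = 256
    n_bands: int = 6
    curvature: float = 35.0          # px of quadratic centerline sag
    retina_thickness: float = 0.28   # fraction of image height
    dome_height: float = 30.0        # CNV/AMD dome amplitude, px
    pocket_count: int = 3            # DME fluid pockets
    bump_count: int = 6              # drusen bumps
    speckle: float = 0.18            # multiplicative speckle std
    seed: int = 0


@dataclass(frozen=True)
class AugmentationPolicy:
    """Random rotation plus Bernoulli horizontal mirror / vertical flip."""

    rotation_degrees: float = 10.0
    mirror_probability: float = 0.5   # left-right
    flip_probability: float = 0.5     # up-down

    def __post_init__(self):
        if not (0 <= self.mirror_probability <= 1
                and 0 <= self.flip_probability <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.rotation_degrees <= 180:
            raise ValueError("rotation range must lie in [0, 180] degrees")


@dataclass
class DatasetManifest:
    """Records of (path, class index, split) plus the frozen class order."""

    records: pd.DataFrame  # columns: path, class_index, split
    class_names: list[str]

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    def paths_and_labels(self, split: str) -> tuple[list[str], np.ndarray]:
        sub = self.subset(split)
        return list(sub["path"]), sub["class_index"].to_numpy()

    def to_csv(self, path) -> None:
        self.records.assign(
            class_name=[self.class_names[i] for i in self.records["class_index"]]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic rendering
# ---------------------------------------------------------------------------

_BAND_LEVELS = np.array([0.42, 0.28, 0.55, 0.30, 0.48, 0.85])  # outer band bright


def _render_image(class_name: str, spec: SyntheticSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """One grayscale cross-section in [0, 1], shape (size, size)."""
    n = spec.image_size
    x = np.arange(n, dtype=np.float64)
    yy = np.arange(n, dtype=np.float64)[:, None]

    # smooth retinal geometry: quadratic centerline + slight tilt
    sag = spec.curvature * (1 + 0.3 * rng.uniform(-1, 1))
    tilt = rng.uniform(-0.06, 0.06)
    center = 0.45 * n + sag * ((x - n / 2) / (n / 2)) ** 2 + tilt * (x - n / 2)
    thickness = spec.retina_thickness * n * (1 + 0.1 * rng.uniform(-1, 1))
    top = center - thickness / 2

    levels = np.resize(_BAND_LEVELS, spec.n_bands)
    widths = rng.uniform(0.7, 1.3, size=spec.n_bands)
    widths = widths / widths.sum() * thickness
    bounds = top + np.concatenate([[0.0], np.cumsum(widths)])[:, None] \
        * np.ones_like(x)  # (n_bands+1, n) column-wise boundaries
    lower = bounds[-1].copy()

    # ---- class-conditional deformations of the outer boundary -------------
    def gaussian_bump(x0, amp, sigma):
        return amp * np.exp(-0.5 * ((x - x0) / sigma) ** 2)

    dome = np.zeros(n)
    if class_name in ("CNV", "AMD"):
        amp = spec.dome_height * (1.3 if class_name == "CNV" else 1.0) \
            * rng.uniform(0.8, 1.2)
        dome = gaussian_bump(rng.uniform(0.35, 0.65) * n, amp,
                             rng.uniform(0.10, 0.16) * n)
    elif class_name == "DRUSEN":
        for _ in range(spec.bump_count + rng.integers(0, 3)):
            dome += gaussian_bump(rng.uniform(0.15, 0.85) * n,
                                  rng.uniform(0.35, 0.6) * spec.dome_height,
                                  rng.uniform(0.02, 0.04) * n)
    # the outer (lowest, brightest) band bulges upward by `dome`
    bounds[-2] = np.minimum(bounds[-2], lower - dome - widths[-1])

    img = np.full((n, n), 0.06)
    for b in range(spec.n_bands):
        inside = (yy >= bounds[b]) & (yy < bounds[b + 1])
        img[inside] = levels[b]
    # bright fill inside the dome (between the raised band top and the floor)
    if class_name in ("CNV", "AMD", "DRUSEN"):
        inside = (yy >= bounds[-2]) & (yy < lower)
        img[inside] = levels[-1]

    # ---- intra-retinal lesions --------------------------------------------
    xx = np.arange(n, dtype=np.float64)[None, :]
    if class_name == "DME":
        for _ in range(spec.pocket_count + rng.integers(0, 2)):
            cx = rng.uniform(0.2, 0.8) * n
            cy = np.interp(cx, x, center) + rng.uniform(-0.3, 0.3) * thickness
            rx = rng.uniform(0.05, 0.10) * n
            ry = rng.uniform(0.03, 0.06) * n
            img[((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1] = 0.05
    elif class_name == "CSR":
        cx = rng.uniform(0.35, 0.65) * n
        cy = np.interp(cx, x, center) + 0.28 * thickness
        rx = rng.uniform(0.18, 0.26) * n
        ry = rng.uniform(0.05, 0.09) * n
        img[((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1] = 0.05
    elif class_name == "DR":
        for _ in range(rng.integers(6, 12)):
            cx = rng.uniform(0.1, 0.9) * n
            cy = np.interp(cx, x, center) + rng.uniform(-0.4, 0.4) * thickness
            r = rng.uniform(0.008, 0.018) * n
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = 0.05
    elif class_name == "MH":
        cx = n / 2 + rng.uniform(-0.05, 0.05) * n
        half_width = rng.uniform(0.05, 0.09) * n
        depth = rng.uniform(0.55, 0.75) * thickness
        wedge = np.maximum(0.0, 1.0 - np.abs(x - cx) / half_width)
        hole_floor = top + depth * wedge
        img[(yy >= top) & (yy < hole_floor)] = 0.06

    img = ndimage.gaussian_filter(img, sigma=1.2)
    img = img * (1.0 + spec.speckle * rng.standard_normal((n, n)))
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir) -> DatasetManifest:
    """Render the tree ``out_dir/{train,val,test}/{CLASS}/*.png`` + manifest.

    Deterministic: identical spec (including seed) → byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    class_names = sorted(spec.classes)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for split in SPLITS:
        count = spec.images_per_class.get(split, 0)
        for ci, cls in enumerate(class_names):
            cls_dir = out_dir / split / cls
            cls_dir.mkdir(parents=True, exist_ok=True)
            for i in range(count):
                img = _render_image(cls, spec, rng)
                path = cls_dir / f"{cls.lower()}_{split}_{i:04d}.png"
                Image.fromarray((img * 255).round().astype(np.uint8),
                                mode="L").save(path)
                rows.append({"path": str(path), "class_index": ci,
                             "split": split})
    manifest = DatasetManifest(pd.DataFrame(rows), class_names)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# loading and preprocessing
# ---------------------------------------------------------------------------

def load_image_folder(root) -> DatasetManifest:
    """Discover a class-per-subfolder tree.

    Accepts either ``root/{train,val,test}/{CLASS}/`` or a flat
    ``root/{CLASS}/`` layout (treated as a single "train" split).  Class
    indices follow lexicographic folder order, so they are stable across
    machines and layouts.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    split_dirs = {s: root / s for s in SPLITS if (root / s).is_dir()}
    if not split_dirs:
        split_dirs = {"train": root}
    class_names: set[str] = set()
    for d in split_dirs.values():
        class_names.update(p.name for p in d.iterdir() if p.is_dir())
    class_names = sorted(class_names)
    if not class_names:
        raise ValueError(f"no class subfolders found under {root}")
    rows = []
    for split, d in split_dirs.items():
        for ci, cls in enumerate(class_names):
            cls_dir = d / cls
            if not cls_dir.is_dir():
                continue
            files = sorted(p for p in cls_dir.iterdir()
                           if p.suffix.lower() in IMAGE_EXTENSIONS)
            if not files:
                warnings.warn(f"class folder {cls_dir} contains no images")
            rows.extend({"path": str(p), "class_index": ci, "split": split}
                        for p in files)
    return DatasetManifest(pd.DataFrame(
        rows, columns=["path", "class_index", "split"]), class_names)


def preprocess(image, size: int = 224, in_channels: int = 1) -> np.ndarray:
    """Resize (bilinear) to size×size and scale into [0, 1].

    `image` may be a path, a PIL image, or an array (uint8/uint16 scaled by
    the max representable value; floats assumed already in [0, 1]).  The
    grayscale result is replicated across ``in_channels``.  Idempotent at
    fixed size.
    """
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as im:
                arr = np.asarray(im.convert("L"))
        except OSError as e:
            raise OSError(f"cannot decode image {image}: {e}") from e
    elif isinstance(image, Image.Image):
        arr = np.asarray(image.convert("L"))
    else:
        arr = np.asarray(image)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    else:
        arr = arr.astype(np.float32)
    if arr.shape != (size, size):
        arr = np.asarray(Image.fromarray(arr, mode="F")
                         .resize((size, size), Image.BILINEAR))
    arr = np.clip(arr, 0.0, 1.0).astype(np.float32)
    return np.repeat(arr[:, :, None], in_channels, axis=2)


def augment(image: np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation (reflect padding) + Bernoulli mirror and flip.

    Meant for the training split only.  A zero-range, zero-probability
    policy is the identity.
    """
    out = image
    if policy.rotation_degrees > 0:
        angle = rng.uniform(-policy.rotation_degrees, policy.rotation_degrees)
        out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
    if policy.mirror_probability and rng.random() < policy.mirror_probability:
        out = out[:, ::-1]
    if policy.flip_probability and rng.random() < policy.flip_probability:
        out = out[::-1, :]
    return np.ascontiguousarray(np.clip(out, 0.0, 1.0), dtype=np.float32)


def class_weights(manifest: DatasetManifest, split: str = "train") -> np.ndarray:
    """Inverse-class-frequency weights normalized to mean 1."""
    sub = manifest.subset(split)
    if sub.empty:
        raise ValueError(f"manifest has no records for split {split!r}")
    counts = np.bincount(sub["class_index"], minlength=len(manifest.class_names))
    if np.any(counts == 0):
        empty = [manifest.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes with no {split} images: {empty}")
    return normalize_class_weights(1.0 / counts)
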