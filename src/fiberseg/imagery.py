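"""Image and mask I/O, resolution normalization, patch extraction.

Images are 8-bit grayscale on disk (PNG/TIFF) with an isotropic pixel size
in micrometers supplied explicitly or through a JSON sidecar
(``{"pixel_size_um": x}``).  Segmentation masks use a three-class encoding
on disk — background=0, myelin=127, axon=255 — and class indices
{0, 1, 2} in memory.

Coordinate convention: row-major, 0-based, origin at the top-left corner.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.exposure import equalize_hist
from skimage.transform import resize

__all__ = [
    "ScalarImage",
    "SegmentationMask",
    "PatchSet",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "decode_mask",
    "encode_mask",
    "resample_image",
    "resample_mask",
    "extract_patches",
    "normalize_patch",
    "split_train_val",
]

#: on-disk gray levels for classes 0 (background), 1 (myelin), 2 (axon)
MASK_LEVELS = (0, 127, 255)

PATCH_SIZE = 512


@dataclass
class ScalarImage:
    """A 2-D grayscale image with an isotropic physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of intensities.  8-bit on disk; any real dtype in memory.
    pixel_size
        Micrometers per pixel, strictly positive.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"expected a non-empty 2-D image, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """A 2-D grid of class indices {0: background, 1: myelin, 2: axon}."""

    classes: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2 or min(self.classes.shape) < 1:
            raise ValueError(f"expected a non-empty 2-D mask, got shape {self.classes.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        bad = np.setdiff1d(np.unique(self.classes), [0, 1, 2])
        if bad.size:
            raise ValueError(f"mask contains classes outside {{0,1,2}}: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_pixel_size(path: Path) -> float:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"no pixel size given and no sidecar {sidecar.name} next to {path.name}"
        )
    with open(sidecar) as fh:
        return float(json.load(fh)["pixel_size_um"])


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        channels = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if all(np.array_equal(channels[..., 0], channels[..., k]) for k in range(1, channels.shape[-1])):
            return channels[..., 0]
    raise ValueError(
        f"{path} is multi-channel with unequal channels; no grayscale conversion is defined"
    )


def read_image(path: str | Path, pixel_size: float | None = None) -> ScalarImage:
    """Read an 8-bit grayscale PNG/TIFF.

    ``pixel_size`` (um/pixel) may be omitted if a JSON sidecar with key
    ``pixel_size_um`` sits next to the image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pixel_size is None:
        pixel_size = _load_pixel_size(path)
    arr = np.asarray(Image.open(path))
    return ScalarImage(_to_gray(arr, path), float(pixel_size))


def write_image(img: ScalarImage, path: str | Path, sidecar: bool = True) -> None:
    """Write as 8-bit PNG/TIFF (values clipped and rounded), plus a pixel-size sidecar."""
    path = Path(path)
    arr = np.clip(np.rint(np.asarray(img.pixels, dtype=float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"pixel_size_um": img.pixel_size}, fh)


def decode_mask(label_image: np.ndarray, pixel_size: float = 1.0) -> SegmentationMask:
    """Map the on-disk gray levels 0/127/255 to class indices 0/1/2."""
    label_image = np.asarray(label_image)
    classes = np.zeros(label_image.shape, dtype=np.uint8)
    known = np.zeros(label_image.shape, dtype=bool)
    for cls, level in enumerate(MASK_LEVELS):
        hit = label_image == level
        classes[hit] = cls
        known |= hit
    if not known.all():
        bad = np.unique(label_image[~known])
        raise ValueError(f"label image contains values outside {MASK_LEVELS}: {bad.tolist()}")
    return SegmentationMask(classes, pixel_size)


def encode_mask(mask: SegmentationMask) -> np.ndarray:
    """Map class indices 0/1/2 back to the 0/127/255 gray levels."""
    return np.asarray(MASK_LEVELS, dtype=np.uint8)[mask.classes]


def read_mask(path: str | Path, pixel_size: float | None = None) -> SegmentationMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pixel_size is None:
        pixel_size = _load_pixel_size(path)
    arr = _to_gray(np.asarray(Image.open(path)), path)
    return decode_mask(arr, float(pixel_size))


def write_mask(mask: SegmentationMask, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    Image.fromarray(encode_mask(mask)).save(path)
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"pixel_size_um": mask.pixel_size}, fh)


def _resampled_shape(shape: tuple[int, int], pixel_size: float, target: float) -> tuple[int, int]:
    out = tuple(int(round(s * pixel_size / target)) for s in shape)
    if min(out) < 1:
        raise ValueError(f"resampling {shape} from {pixel_size} to {target} um/px collapses a dimension")
    return out


def resample_image(img: ScalarImage, target_pixel_size: float) -> ScalarImage:
    """Bilinearly resample to a new isotropic pixel size.

    Resampling to the current pixel size is an exact identity.
    """
    if not target_pixel_size > 0:
        raise ValueError("target_pixel_size must be > 0")
    if target_pixel_size == img.pixel_size:
        return ScalarImage(img.pixels.copy(), img.pixel_size)
    shape = _resampled_shape(img.shape, img.pixel_size, target_pixel_size)
    out = resize(np.asarray(img.pixels, dtype=float), shape, order=1,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    return ScalarImage(out, target_pixel_size)


def resample_mask(mask: SegmentationMask, target_pixel_size: float) -> SegmentationMask:
    """Nearest-neighbor resampling so labels stay in {0, 1, 2}."""
    if not target_pixel_size > 0:
        raise ValueError("target_pixel_size must be > 0")
    if target_pixel_size == mask.pixel_size:
        return SegmentationMask(mask.classes.copy(), mask.pixel_size)
    shape = _resampled_shape(mask.shape, mask.pixel_size, target_pixel_size)
    out = resize(mask.classes, shape, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True).astype(mask.classes.dtype)
    return SegmentationMask(out, target_pixel_size)


def mirror_pad(arr: np.ndarray, pad: tuple[tuple[int, int], tuple[int, int]]) -> np.ndarray:
    """Mirror-pad a 2-D array, chaining reflections when the pad exceeds the side."""
    out = arr
    pad = [list(p) for p in pad]
    while any(b or a for b, a in pad):
        step = []
        for axis, (before, after) in enumerate(pad):
            limit = out.shape[axis] - 1
            b = min(before, limit)
            a = min(after, limit)
            pad[axis][0] -= b
            pad[axis][1] -= a
            step.append((b, a))
        if all(b == 0 and a == 0 for b, a in step):  # 1-pixel side: fall back to edge
            step = [(b, a) for (b, a) in pad]
            out = np.pad(out, step, mode="edge")
            break
        out = np.pad(out, step, mode="reflect")
    return out


@dataclass
class PatchSet:
    """Paired image/mask patches with their origins in the resampled frame."""

    patches: list[tuple[np.ndarray, np.ndarray]]
    origins: list[tuple[int, int]]
    splits: list[str] = field(default_factory=list)
    pixel_size: float = 1.0
    patch_size: int = PATCH_SIZE
    source_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for im, ma in self.patches:
            if im.shape != (self.patch_size,) * 2 or ma.shape != (self.patch_size,) * 2:
                raise ValueError(f"all patches must be {self.patch_size}x{self.patch_size}")
        if not self.splits:
            self.splits = ["train"] * len(self.patches)

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, split: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for p, s in zip(self.patches, self.splits) if s == split]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, ((im, ma), (r, c), split) in enumerate(zip(self.patches, self.origins, self.splits)):
            Image.fromarray(np.clip(np.rint(im), 0, 255).astype(np.uint8)).save(out_dir / f"image_{i:04d}.png")
            Image.fromarray(np.asarray(MASK_LEVELS, dtype=np.uint8)[ma]).save(out_dir / f"mask_{i:04d}.png")
            rows.append({"patch": i, "origin_row": r, "origin_col": c, "split": split})
        pd.DataFrame(rows).to_csv(out_dir / "index.tsv", sep="\t", index=False)
        with open(out_dir / "patchset.json", "w") as fh:
            json.dump({"pixel_size_um": self.pixel_size, "patch_size": self.patch_size,
                       "source_shape": list(self.source_shape) if self.source_shape else None}, fh)

    @classmethod
    def load(cls, in_dir: str | Path) -> "PatchSet":
        in_dir = Path(in_dir)
        index = pd.read_csv(in_dir / "index.tsv", sep="\t")
        with open(in_dir / "patchset.json") as fh:
            meta = json.load(fh)
        patches, origins, splits = [], [], []
        for row in index.itertuples():
            im = np.asarray(Image.open(in_dir / f"image_{row.patch:04d}.png"))
            ma = decode_mask(np.asarray(Image.open(in_dir / f"mask_{row.patch:04d}.png"))).classes
            patches.append((im, ma))
            origins.append((int(row.origin_row), int(row.origin_col)))
            splits.append(str(row.split))
        src = meta.get("source_shape")
        return cls(patches, origins, splits, float(meta["pixel_size_um"]),
                   int(meta["patch_size"]), tuple(src) if src else None)


def extract_patches(img: ScalarImage, mask: SegmentationMask,
                    patch_size: int = PATCH_SIZE) -> PatchSet:
    """Tile an image/mask pair into a non-overlapping grid of square patches.

    The canvas is mirror-padded (bottom/right) up to the next multiple of
    ``patch_size``; origins are inclusive top-left corners in the padded frame,
    so restitching the patches and cropping to the original shape recovers the
    input exactly.
    """
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    if img.pixel_size != mask.pixel_size:
        raise ValueError("image and mask pixel sizes differ")
    h, w = img.shape
    ph = (-h) % patch_size
    pw = (-w) % patch_size
    im = mirror_pad(np.asarray(img.pixels), ((0, ph), (0, pw)))
    ma = mirror_pad(np.asarray(mask.classes), ((0, ph), (0, pw)))
    patches, origins = [], []
    for r in range(0, h + ph, patch_size):
        for c in range(0, w + pw, patch_size):
            patches.append((im[r:r + patch_size, c:c + patch_size].copy(),
                            ma[r:r + patch_size, c:c + patch_size].copy()))
            origins.append((r, c))
    return PatchSet(patches, origins, pixel_size=img.pixel_size,
                    patch_size=patch_size, source_shape=(h, w))


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Histogram-equalize (global, 256 bins) then standardize a patch.

    The output has zero mean and unit variance; the variance is floored at
    1e-8, so a constant patch maps to all zeros.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.max() > patch.min():
        patch = equalize_hist(patch, nbins=256)
    mu = patch.mean()
    sd = np.sqrt(max(patch.var(), 1e-8))
    return (patch - mu) / sd


def split_train_val(patchset: PatchSet, fraction: float = 0.7,
                    seed: int | None = 0) -> PatchSet:
    """Randomly tag patches train/validation; train count = round(fraction * n)."""
    n = len(patchset)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    n_train = int(round(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    splits = ["validation"] * n
    for i in order[:n_train]:
        splits[i] = "train"
    if n_train == n:
        warnings.warn("validation split is empty", stacklevel=2)
    if n_train == 0:
        warnings.warn("train split is empty", stacklevel=2)
    return PatchSet(patchset.patches, patchset.origins, splits,
                    patchset.pixel_size, patchset.patch_size, patchset.source_shape)
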