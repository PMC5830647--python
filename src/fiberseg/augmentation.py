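"""Randomized training-time transformations applied jointly to image and label.

Six transforms — shift, rotation, rescale, flip, blur, elastic deformation —
are composed in that order, each applied independently with a configurable
probability.  Geometric transforms use mirror fill and warp the image
bilinearly but the label with nearest-neighbor, so labels stay in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, rotate, shift
from skimage.transform import resize

from .imagery import mirror_pad

__all__ = [
    "AugmentationSpec",
    "random_shift",
    "random_rotation",
    "random_rescale",
    "random_flip",
    "random_blur",
    "elastic_deform",
    "augment",
]


@dataclass
class AugmentationSpec:
    """Parameter ranges of the augmentation strategy.

    Shift offsets are a fraction of the patch side; rotation angles in
    degrees; rescale factors dimensionless; blur and elastic sigma in pixels.
    The elastic displacement field is per-pixel uniform noise in [-1, 1],
    smoothed with a Gaussian of ``elastic_sigma`` and scaled by a coefficient
    drawn uniformly from ``elastic_alpha_range``.
    """

    shift_max_fraction: float = 0.10
    rotation_range: tuple[float, float] = (5.0, 89.0)
    rescale_range: tuple[float, float] = (1.0 / 1.2, 1.2)
    flip_modes: tuple[str, ...] = ("horizontal", "vertical")
    blur_sd_range: tuple[float, float] = (0.0, 4.0)
    elastic_alpha_range: tuple[float, float] = (1.0, 8.0)
    elastic_sigma: float = 4.0
    probability: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "shift_max_fraction": self.shift_max_fraction,
            "rotation_range": list(self.rotation_range),
            "rescale_range": list(self.rescale_range),
            "flip_modes": list(self.flip_modes),
            "blur_sd_range": list(self.blur_sd_range),
            "elastic_alpha_range": list(self.elastic_alpha_range),
            "elastic_sigma": self.elastic_sigma,
            "probability": self.probability,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationSpec":
        d = dict(d)
        for key in ("rotation_range", "rescale_range", "flip_modes",
                    "blur_sd_range", "elastic_alpha_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def random_shift(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 max_fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Translate both arrays by per-axis offsets uniform in [0, max_fraction*side],
    each with a random sign; mirror fill."""
    side = img.shape[0]
    off = rng.uniform(0.0, max_fraction * side, size=2) * rng.choice([-1.0, 1.0], size=2)
    img = shift(np.asarray(img, dtype=float), off, order=1, mode="reflect")
    mask = shift(mask, off, order=0, mode="reflect")
    return img, mask


def random_rotation(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                    angle_range: tuple[float, float] = (5.0, 89.0),
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate by an angle with magnitude uniform in ``angle_range``, random sign."""
    angle = rng.uniform(*angle_range) * rng.choice([-1.0, 1.0])
    img = rotate(np.asarray(img, dtype=float), angle, reshape=False, order=1, mode="reflect")
    mask = rotate(mask, angle, reshape=False, order=0, mode="reflect")
    return img, mask


def random_rescale(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                   factor_range: tuple[float, float] = (1.0 / 1.2, 1.2),
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Zoom by a factor uniform in ``factor_range``, keeping the output side fixed.

    Factor > 1: the central round(side/factor) region is upscaled back to the
    full side.  Factor < 1: the whole patch is downscaled and mirror-padded
    back.  Factor 1 is the identity.
    """
    side = img.shape[0]
    f = rng.uniform(*factor_range)
    if f == 1.0:
        return np.asarray(img, dtype=float), mask
    if f > 1.0:
        crop = int(round(side / f))
        lo = (side - crop) // 2
        sl = slice(lo, lo + crop)
        img = resize(np.asarray(img[sl, sl], dtype=float), (side, side), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
        mask = resize(mask[sl, sl], (side, side), order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True).astype(mask.dtype)
        return img, mask
    small = int(round(side * f))
    img_s = resize(np.asarray(img, dtype=float), (small, small), order=1,
                   mode="edge", anti_aliasing=False, preserve_range=True)
    mask_s = resize(mask, (small, small), order=0, mode="edge",
                    anti_aliasing=False, preserve_range=True).astype(mask.dtype)
    before = (side - small) // 2
    after = side - small - before
    pad = ((before, after), (before, after))
    return mirror_pad(img_s, pad), mirror_pad(mask_s, pad)


def random_flip(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                modes: tuple[str, ...] = ("horizontal", "vertical"),
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mirror both arrays along one axis chosen uniformly from ``modes``."""
    mode = modes[rng.integers(len(modes))]
    axis = 1 if mode == "horizontal" else 0
    return np.flip(img, axis=axis).copy(), np.flip(mask, axis=axis).copy()


def random_blur(img: np.ndarray, rng: np.random.Generator,
                sd_range: tuple[float, float] = (0.0, 4.0)) -> np.ndarray:
    """Gaussian-blur the image only, SD uniform in ``sd_range``."""
    sd = rng.uniform(*sd_range)
    img = np.asarray(img, dtype=float)
    return gaussian_filter(img, sd) if sd > 0 else img


def elastic_deform(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                   alpha_range: tuple[float, float] = (1.0, 8.0),
                   sigma: float = 4.0, alpha: float | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Warp by a smooth random displacement field.

    Per-pixel displacements are uniform in [-1, 1], Gaussian-smoothed with
    ``sigma`` and scaled by ``alpha`` (drawn uniformly from ``alpha_range``
    unless given), so the displacement magnitude never exceeds ``alpha``.
    """
    if alpha is None:
        alpha = rng.uniform(*alpha_range)
    h, w = img.shape
    dr = gaussian_filter(rng.uniform(-1, 1, size=(h, w)), sigma) * alpha
    dc = gaussian_filter(rng.uniform(-1, 1, size=(h, w)), sigma) * alpha
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + dr, cc + dc])
    img = map_coordinates(np.asarray(img, dtype=float), coords, order=1, mode="reflect")
    mask = map_coordinates(mask, coords, order=0, mode="reflect")
    return img, mask


def augment(img: np.ndarray, mask: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply shift -> rotation -> rescale -> flip -> blur -> elastic, each with
    probability ``spec.probability``; deterministic under a seeded generator."""
    img = np.asarray(img, dtype=float)
    if rng.random() < spec.probability:
        img, mask = random_shift(img, mask, rng, spec.shift_max_fraction)
    if rng.random() < spec.probability:
        img, mask = random_rotation(img, mask, rng, spec.rotation_range)
    if rng.random() < spec.probability:
        img, mask = random_rescale(img, mask, rng, spec.rescale_range)
    if rng.random() < spec.probability:
        img, mask = random_flip(img, mask, rng, spec.flip_modes)
    if rng.random() < spec.probability:
        img = random_blur(img, rng, spec.blur_sd_range)
    if rng.random() < spec.probability:
        img, mask = elastic_deform(img, mask, rng, spec.elastic_alpha_range,
                                   spec.elastic_sigma)
    return img, mask
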