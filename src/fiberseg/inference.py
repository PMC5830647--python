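"""Overlap-tile segmentation of arbitrarily sized images.

The image is resampled to the model's working pixel size, mirror-padded by
the overlap ``d`` on every side (plus a remainder so the interior is a
multiple of the emitted core), and segmented window by window: inference
runs on each ``window x window`` patch but only the central
``(window - 2d) x (window - 2d)`` core of the probabilities is kept, which
suppresses border artifacts around partially visible fibers.  Cores tile
the image exactly once; the stitched class probabilities are resampled
bilinearly back to the native resolution before the per-pixel argmax (ties
broken toward the lowest class index), so the output mask has the input's
shape and pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .imagery import ScalarImage, SegmentationMask, mirror_pad, normalize_patch, resample_image
from .network import UNet

__all__ = ["TilingSpec", "Tile", "plan_tiles", "segment_image"]


@dataclass
class TilingSpec:
    """Window geometry for overlap-tile inference.

    ``window`` is the inference patch side; ``overlap`` is the margin ``d``
    discarded on each side of a window, so the emitted core has side
    ``window - 2 * overlap``.
    """

    window: int = 512
    overlap: int = 25

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window / 2:
            raise ValueError(
                f"overlap must satisfy 0 <= d < window/2, got d={self.overlap}")

    @property
    def core(self) -> int:
        return self.window - 2 * self.overlap


@dataclass
class Tile:
    """One inference window over the padded image frame.

    ``window_origin`` is the top-left corner of the full window in the padded
    frame; ``core_slice`` addresses the emitted region in the unpadded
    (core-multiple) frame.
    """

    window_origin: tuple[int, int]
    core_slice: tuple[slice, slice]


def plan_tiles(height: int, width: int, spec: TilingSpec | None = None) -> list[Tile]:
    """Tile an ``height x width`` image with emitted cores that partition it.

    The image is assumed padded by ``overlap`` on all sides plus a bottom/right
    remainder up to the next core multiple; windows advance by the core size,
    and every padded-interior pixel is emitted exactly once.
    """
    spec = spec or TilingSpec()
    core = spec.core
    n_rows = int(np.ceil(height / core))
    n_cols = int(np.ceil(width / core))
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            tiles.append(Tile(
                window_origin=(r * core, c * core),
                core_slice=(slice(r * core, (r + 1) * core),
                            slice(c * core, (c + 1) * core)),
            ))
    return tiles


def segment_image(img: ScalarImage, model: UNet,
                  tiling: TilingSpec | None = None,
                  ) -> tuple[SegmentationMask, np.ndarray]:
    """Segment an image of any size and pixel size.

    Returns the 3-class mask at the image's native resolution together with
    the stitched per-class probability maps ``(3, H', W')`` at the model's
    working resolution.
    """
    tiling = tiling or TilingSpec()
    spec = model.spec
    work = resample_image(img, spec.training_pixel_size)
    h, w = work.shape
    core, d = tiling.core, tiling.overlap
    rem_h = (-h) % core
    rem_w = (-w) % core
    padded = mirror_pad(np.asarray(work.pixels, dtype=float),
                        ((d, d + rem_h), (d, d + rem_w)))

    model.eval()
    probs = np.zeros((spec.n_classes, h + rem_h, w + rem_w))
    for tile in plan_tiles(h, w, tiling):
        r0, c0 = tile.window_origin
        window = padded[r0:r0 + tiling.window, c0:c0 + tiling.window]
        p = model.forward(normalize_patch(window)[None, None])[0]
        probs[(slice(None),) + tile.core_slice] = p[:, d:d + core, d:d + core]
    probs = probs[:, :h, :w]

    if img.shape != (h, w):
        native = np.stack([
            resize(probs[c], img.shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
            for c in range(spec.n_classes)])
    else:
        native = probs
    classes = native.argmax(axis=0).astype(np.uint8)  # argmax ties -> lowest class
    return SegmentationMask(classes, img.pixel_size), probs
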