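"""Synthetic electron-microscopy-like images of myelinated fibers.

A myelinated fiber is modelled as an axon disk of diameter ``d`` wrapped in
a myelin annulus out to the fiber radius ``d / (2 g)``, where ``g`` is the
fiber's g-ratio (inner/outer diameter, typically 0.5-0.75 in healthy white
matter).  Populations are placed by dart throwing with rejection so fibers
never overlap, rasterized to exact three-class ground-truth masks, and
rendered with class-wise mean intensities, Gaussian blur and Gaussian noise
to mimic osmium-stained SEM (myelin-bright) or TEM (myelin-dark) contrast.

Everything is deterministic under a seed, so the generator doubles as the
ground truth for morphometry validation: per-fiber centers, diameters and
g-ratios are exported as a TSV table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .imagery import ScalarImage, SegmentationMask, write_image, write_mask

__all__ = [
    "DiameterDistribution",
    "GRatioDistribution",
    "FiberPopulation",
    "RenderSpec",
    "sample_population",
    "rasterize",
    "render",
    "generate_dataset",
]


@dataclass
class DiameterDistribution:
    """Log-normal axon diameters (um). ``median`` is exp(mu) of the underlying
    normal; ``minimum`` truncates the lower tail by rejection."""

    median: float = 3.0
    log_sd: float = 0.3
    minimum: float | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        d = np.exp(rng.normal(np.log(self.median), self.log_sd, size=n))
        if self.minimum is not None:
            if self.minimum >= self.median:
                raise ValueError("minimum must lie below the median")
            for _ in range(100):
                low = d < self.minimum
                if not low.any():
                    break
                d[low] = np.exp(rng.normal(np.log(self.median), self.log_sd,
                                           size=int(low.sum())))
        return d


@dataclass
class GRatioDistribution:
    """Truncated-normal g-ratio, bounded inside (0, 1)."""

    mean: float = 0.7
    sd: float = 0.05
    low: float = 0.4
    high: float = 0.95

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass
class FiberPopulation:
    """Non-overlapping fibers on a rectangular canvas.

    Centers are (row, col) in micrometers from the top-left canvas corner.
    """

    centers: np.ndarray          # (n, 2) um
    axon_diameters: np.ndarray   # (n,) um
    g_ratios: np.ndarray         # (n,) in (0, 1)
    canvas_size: tuple[float, float]  # (height, width) um
    pixel_size: float            # um per pixel

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.axon_diameters = np.asarray(self.axon_diameters, dtype=float)
        self.g_ratios = np.asarray(self.g_ratios, dtype=float)
        if np.any(self.axon_diameters <= 0):
            raise ValueError("axon diameters must be > 0")
        if np.any((self.g_ratios <= 0) | (self.g_ratios >= 1)):
            raise ValueError("g-ratios must lie in (0, 1)")

    @property
    def n_fibers(self) -> int:
        return len(self.axon_diameters)

    @property
    def fiber_radii(self) -> np.ndarray:
        """Outer (myelin) radii in um: d / (2 g)."""
        return self.axon_diameters / (2.0 * self.g_ratios)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fiber": np.arange(self.n_fibers),
            "center_row_um": self.centers[:, 0],
            "center_col_um": self.centers[:, 1],
            "axon_diameter_um": self.axon_diameters,
            "g_ratio": self.g_ratios,
        })


@dataclass
class RenderSpec:
    """Class-wise intensity model for rendering a mask into an image.

    ``polarity='sem'`` renders myelin bright on a mid-gray background;
    ``'tem'`` renders myelin dark.  Intensities are on the 8-bit scale.
    """

    polarity: str = "sem"
    background: float | None = None
    myelin: float | None = None
    axon: float | None = None
    noise_sd: float = 8.0
    blur_sd: float = 0.7

    _DEFAULTS = {"sem": (120.0, 220.0, 40.0), "tem": (170.0, 40.0, 210.0)}

    def __post_init__(self) -> None:
        if self.polarity not in self._DEFAULTS:
            raise ValueError(f"polarity must be 'sem' or 'tem', got {self.polarity!r}")
        bg, my, ax = self._DEFAULTS[self.polarity]
        self.background = bg if self.background is None else float(self.background)
        self.myelin = my if self.myelin is None else float(self.myelin)
        self.axon = ax if self.axon is None else float(self.axon)
        for v in (self.background, self.myelin, self.axon):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise ValueError("noise_sd and blur_sd must be >= 0")

    @property
    def levels(self) -> np.ndarray:
        return np.array([self.background, self.myelin, self.axon], dtype=float)


def sample_population(n_fibers: int,
                      diameter_distribution: DiameterDistribution | None = None,
                      g_ratio_distribution: GRatioDistribution | None = None,
                      canvas_size: float | tuple[float, float] = 102.4,
                      pixel_size: float = 0.1,
                      seed: int | None = 0,
                      margin: float | None = None,
                      max_tries: int = 10_000) -> FiberPopulation:
    """Place ``n_fibers`` non-overlapping fibers by dart throwing.

    Each fiber's diameter and g-ratio are drawn first, then centers are
    sampled uniformly (largest fibers placed first) and rejected while the
    outer circles would overlap or cross the canvas edge.  ``margin`` is the
    guaranteed background gap between fibers (default 2 pixels, which keeps
    rasterized fibers 8-disconnected).

    Raises ``RuntimeError`` if a fiber cannot be placed within ``max_tries``
    attempts (canvas too crowded).
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if np.isscalar(canvas_size):
        canvas_size = (float(canvas_size), float(canvas_size))
    diameter_distribution = diameter_distribution or DiameterDistribution()
    g_ratio_distribution = g_ratio_distribution or GRatioDistribution()
    if margin is None:
        margin = 2.0 * pixel_size
    rng = np.random.default_rng(seed)

    diameters = diameter_distribution.sample(n_fibers, rng)
    g_ratios = g_ratio_distribution.sample(n_fibers, rng)
    radii = diameters / (2.0 * g_ratios)
    order = np.argsort(-radii)  # big fibers first: easier packing

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    centers = np.zeros((n_fibers, 2))
    for idx in order:
        r = radii[idx]
        lo = np.array([r, r])
        hi = np.array([canvas_size[0] - r, canvas_size[1] - r])
        if np.any(hi <= lo):
            raise RuntimeError(f"fiber of outer radius {r:.2f} um does not fit the canvas")
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            if all(np.hypot(*(c - pc)) >= r + pr + margin
                   for pc, pr in zip(placed_centers, placed_radii)):
                break
        else:
            raise RuntimeError(
                f"could not place fiber {idx} after {max_tries} tries; canvas too crowded")
        placed_centers.append(c)
        placed_radii.append(r)
        centers[idx] = c
    return FiberPopulation(centers, diameters, g_ratios, canvas_size, pixel_size)


def rasterize(pop: FiberPopulation) -> SegmentationMask:
    """Rasterize a population to a three-class mask by pixel-center sampling.

    A pixel belongs to the axon (class 2) if its center lies within the axon
    radius of some fiber, to myelin (class 1) if within the outer radius, and
    to background (class 0) otherwise.  Pixel (i, j) has its center at
    ((i + 0.5) * pixel_size, (j + 0.5) * pixel_size).
    """
    ps = pop.pixel_size
    shape = (int(round(pop.canvas_size[0] / ps)), int(round(pop.canvas_size[1] / ps)))
    classes = np.zeros(shape, dtype=np.uint8)
    if pop.n_fibers == 0:
        return SegmentationMask(classes, ps)
    for c, d, g in zip(pop.centers, pop.axon_diameters, pop.g_ratios):
        r_axon = d / 2.0
        r_out = d / (2.0 * g)
        r0 = max(int(np.floor((c[0] - r_out) / ps)) - 1, 0)
        r1 = min(int(np.ceil((c[0] + r_out) / ps)) + 1, shape[0])
        c0 = max(int(np.floor((c[1] - r_out) / ps)) - 1, 0)
        c1 = min(int(np.ceil((c[1] + r_out) / ps)) + 1, shape[1])
        rows = (np.arange(r0, r1) + 0.5) * ps - c[0]
        cols = (np.arange(c0, c1) + 0.5) * ps - c[1]
        dist2 = rows[:, None] ** 2 + cols[None, :] ** 2
        sub = classes[r0:r1, c0:c1]
        sub[dist2 <= r_out ** 2] = 1
        sub[dist2 <= r_axon ** 2] = 2
    return SegmentationMask(classes, ps)


def render(mask: SegmentationMask, spec: RenderSpec | None = None,
           seed: int | None = 0) -> ScalarImage:
    """Render a mask into an intensity image: class means -> blur -> noise -> clip."""
    spec = spec or RenderSpec()
    rng = np.random.default_rng(seed)
    img = spec.levels[mask.classes]
    if spec.blur_sd > 0:
        img = gaussian_filter(img, spec.blur_sd)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ScalarImage(np.clip(img, 0, 255), mask.pixel_size)


def generate_dataset(n_images: int,
                     out_dir: str | Path,
                     n_fibers: int = 60,
                     diameter_distribution: DiameterDistribution | None = None,
                     g_ratio_distribution: GRatioDistribution | None = None,
                     canvas_size: float | tuple[float, float] = 102.4,
                     pixel_size: float = 0.1,
                     render_spec: RenderSpec | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Write ``n_images`` paired image/mask PNGs plus a per-fiber morphometry TSV.

    Returns the morphometry table (one row per fiber, with its source image).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    frames = []
    for i in range(n_images):
        pop_seed, render_seed = root.integers(2**31, size=2)
        pop = sample_population(n_fibers, diameter_distribution, g_ratio_distribution,
                                canvas_size, pixel_size, seed=int(pop_seed))
        mask = rasterize(pop)
        img = render(mask, render_spec, seed=int(render_seed))
        write_image(img, out_dir / f"image_{i:03d}.png")
        write_mask(mask, out_dir / f"mask_{i:03d}.png")
        frame = pop.to_frame()
        frame.insert(0, "image", i)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out_dir / "morphometry.tsv", sep="\t", index=False,
                 float_format="%.6f")
    with open(out_dir / "dataset.json", "w") as fh:
        json.dump({"n_images": n_images, "n_fibers": n_fibers,
                   "pixel_size_um": pixel_size, "seed": seed}, fh)
    return table
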