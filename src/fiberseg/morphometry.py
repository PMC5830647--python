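"""Morphometric quantities from a 3-class axon/myelin mask.

Per-axon records (area, centroid, equivalent diameter ``sqrt(4*Area/pi)``)
come from 8-connected components of the axon class.  Aggregate maps are
computed on a square grid (default 50 x 50 um^2 bins):

- axon diameter mean and SD over the axons whose centroid falls in the bin;
- axon density, centroid count per mm^2;
- axon and myelin volume fractions (AVF, MVF), the fraction of bin pixels
  of each class;
- aggregate g-ratio, estimated as ``sqrt(1 / (1 + MVF/AVF))``.

Bins with no axon pixels, partial edge bins, and bins whose optional region
mask coverage is below 50% are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .imagery import SegmentationMask

__all__ = ["AxonRecord", "MorphometryGrid", "axon_table", "grid_metrics",
           "recover_population"]

AXON_CLASS = 2
MYELIN_CLASS = 1


@dataclass
class AxonRecord:
    """One axon object: centroid and area in physical units."""

    object_id: int
    centroid_row_um: float
    centroid_col_um: float
    area_um2: float

    @property
    def equivalent_diameter_um(self) -> float:
        return float(np.sqrt(4.0 * self.area_um2 / np.pi))


def axon_table(mask: SegmentationMask) -> pd.DataFrame:
    """Per-axon morphometry: one row per 8-connected axon component.

    Columns: object_id, centroid_row_um, centroid_col_um, area_um2,
    equivalent_diameter_um.  Centroids are in micrometers from the top-left
    corner (pixel centers at (i + 0.5) * pixel_size).
    """
    ps = mask.pixel_size
    lab = label(mask.classes == AXON_CLASS, connectivity=2)
    rows = []
    for region in regionprops(lab):
        area = region.area * ps ** 2
        rows.append({
            "object_id": region.label,
            "centroid_row_um": (region.centroid[0] + 0.5) * ps,
            "centroid_col_um": (region.centroid[1] + 0.5) * ps,
            "area_um2": area,
            "equivalent_diameter_um": float(np.sqrt(4.0 * area / np.pi)),
        })
    return pd.DataFrame(rows, columns=["object_id", "centroid_row_um",
                                       "centroid_col_um", "area_um2",
                                       "equivalent_diameter_um"])


@dataclass
class MorphometryGrid:
    """Binned maps of the five morphometric metrics.

    Each field is a 2-D array over bins; ``valid`` marks bins that are fully
    inside the image, have axon content, and meet the region-mask coverage
    threshold.  Bins with no axons have NaN diameter statistics.
    """

    bin_size_um: float
    diameter_mean: np.ndarray
    diameter_sd: np.ndarray
    density_per_mm2: np.ndarray
    avf: np.ndarray
    mvf: np.ndarray
    g_ratio: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.avf.shape

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.shape[0]):
            for c in range(self.shape[1]):
                rows.append({
                    "bin_row": r, "bin_col": c,
                    "diameter_mean_um": self.diameter_mean[r, c],
                    "diameter_sd_um": self.diameter_sd[r, c],
                    "density_per_mm2": self.density_per_mm2[r, c],
                    "avf": self.avf[r, c], "mvf": self.mvf[r, c],
                    "g_ratio": self.g_ratio[r, c], "valid": bool(self.valid[r, c]),
                })
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "morphometry_grid.tsv", sep="\t",
                               index=False, float_format="%.6f")


def grid_metrics(mask: SegmentationMask, bin_size_um: float = 50.0,
                 region_mask: np.ndarray | None = None,
                 coverage_threshold: float = 0.5) -> MorphometryGrid:
    """Aggregate morphometrics over square bins of ``bin_size_um``.

    Axons are assigned to bins by centroid, so each axon is counted exactly
    once; densities divide the centroid count by the bin area in mm^2.
    Partial edge bins (image side not a bin multiple) are flagged invalid
    rather than rescaled.
    """
    ps = mask.pixel_size
    bin_px = int(round(bin_size_um / ps))
    if bin_px < 2:
        raise ValueError(f"bin of {bin_size_um} um is under 2 pixels at {ps} um/px")
    h, w = mask.shape
    n_rows = int(np.ceil(h / bin_px))
    n_cols = int(np.ceil(w / bin_px))
    shape = (n_rows, n_cols)

    diameter_mean = np.full(shape, np.nan)
    diameter_sd = np.full(shape, np.nan)
    density = np.zeros(shape)
    avf = np.zeros(shape)
    mvf = np.zeros(shape)
    g_ratio = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    table = axon_table(mask)
    if len(table):
        cent_bin_r = (table["centroid_row_um"] / (bin_px * ps)).astype(int).clip(0, n_rows - 1)
        cent_bin_c = (table["centroid_col_um"] / (bin_px * ps)).astype(int).clip(0, n_cols - 1)
    bin_area_mm2 = (bin_px * ps / 1000.0) ** 2

    for r in range(n_rows):
        for c in range(n_cols):
            rs = slice(r * bin_px, (r + 1) * bin_px)
            cs = slice(c * bin_px, (c + 1) * bin_px)
            sub = mask.classes[rs, cs]
            full = sub.size == bin_px ** 2
            n_px = sub.size
            avf[r, c] = np.mean(sub == AXON_CLASS)
            mvf[r, c] = np.mean(sub == MYELIN_CLASS)
            if len(table):
                here = table[(cent_bin_r == r) & (cent_bin_c == c)]
                density[r, c] = len(here) / bin_area_mm2
                if len(here):
                    d = here["equivalent_diameter_um"].to_numpy()
                    diameter_mean[r, c] = d.mean()
                    diameter_sd[r, c] = d.std(ddof=0)
            if avf[r, c] > 0:
                g_ratio[r, c] = np.sqrt(1.0 / (1.0 + mvf[r, c] / avf[r, c]))
            covered = True
            if region_mask is not None:
                covered = np.mean(np.asarray(region_mask, dtype=bool)[rs, cs]) >= coverage_threshold
            valid[r, c] = full and avf[r, c] > 0 and covered
    return MorphometryGrid(bin_size_um, diameter_mean, diameter_sd, density,
                           avf, mvf, g_ratio, valid)


def recover_population(mask: SegmentationMask, truth: pd.DataFrame,
                       bin_size_um: float = 50.0) -> dict:
    """Compare morphometry measured on a synthetic mask with generator truth.

    ``truth`` is the generator's per-fiber table (center_row_um,
    center_col_um, axon_diameter_um, g_ratio).  Measured axons are matched to
    generated fibers by nearest centroid; per-fiber g-ratios are measured as
    ``sqrt(axon area / fiber area)`` over each connected fiber (axon+myelin)
    region.  Returns counts, diameter bias/RMSE, per-fiber g bias/RMSE, and
    the mean grid g over valid bins.
    """
    measured = axon_table(mask)
    n_meas, n_true = len(measured), len(truth)
    report: dict = {"n_measured": n_meas, "n_generated": n_true}
    if n_meas == 0 or n_true == 0:
        return report

    mc = measured[["centroid_row_um", "centroid_col_um"]].to_numpy()
    tc = truth[["center_row_um", "center_col_um"]].to_numpy()
    dist = np.linalg.norm(mc[:, None] - tc[None], axis=2)
    nearest = dist.argmin(axis=1)
    d_meas = measured["equivalent_diameter_um"].to_numpy()
    d_true = truth["axon_diameter_um"].to_numpy()[nearest]
    report["diameter_bias_um"] = float(np.mean(d_meas - d_true))
    report["diameter_rmse_um"] = float(np.sqrt(np.mean((d_meas - d_true) ** 2)))

    # per-fiber g from connected axon+myelin regions (fibers do not overlap)
    fiber_lab = label(mask.classes > 0, connectivity=2)
    g_meas = np.full(n_meas, np.nan)
    axon_lab = label(mask.classes == AXON_CLASS, connectivity=2)
    for i, row in measured.iterrows():
        r = int(round(row["centroid_row_um"] / mask.pixel_size - 0.5))
        c = int(round(row["centroid_col_um"] / mask.pixel_size - 0.5))
        fl = fiber_lab[r, c]
        if fl == 0:
            continue
        region = fiber_lab == fl
        axon_px = np.count_nonzero(mask.classes[region] == AXON_CLASS)
        g_meas[i] = np.sqrt(axon_px / np.count_nonzero(region))
    g_true = truth["g_ratio"].to_numpy()[nearest]
    ok = np.isfinite(g_meas)
    report["g_bias"] = float(np.mean(g_meas[ok] - g_true[ok]))
    report["g_rmse"] = float(np.sqrt(np.mean((g_meas[ok] - g_true[ok]) ** 2)))

    grid = grid_metrics(mask, bin_size_um)
    if grid.valid.any():
        report["grid_g_mean"] = float(np.nanmean(grid.g_ratio[grid.valid]))
        report["grid_density_mean_per_mm2"] = float(np.mean(grid.density_per_mm2[grid.valid]))
    return report
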