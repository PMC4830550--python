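"""Reference crop height model (CHMREF) from terrain and canopy point clouds.

The reference surface is built in five stages, mirroring how dense
laser-scanning surveys of crop stands are processed:

1. ground filtering of the (early-season) terrain scan and moving-planes
   interpolation to a digital terrain model (DTM);
2. a crop surface model (CSM) as the per-cell 99th percentile of canopy
   elevations (a robust stand-in for the per-cell maximum);
3. the crop height model CHM = CSM - DTM, in centimeters;
4. local-maximum filtering with a small circular kernel (plant spacing) and
   a larger one (row spacing); cells where the two differ by more than a
   threshold are assumed to sample lower leaves and are removed;
5. a renormalized Gaussian convolution that smooths the surviving cells and
   fills the removed ones, yielding a seamless CHMREF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import NODATA, PointCloud, RasterGrid, ValidationError


@dataclass
class ChmParams:
    """Tunables of the reference-CHM derivation.

    Defaults follow the survey design this package emulates: 50 cm grid,
    99th-percentile CSM, 15 cm / 80 cm kernels (plant and row spacing) and a
    10 cm between-kernel difference threshold.
    """

    cell: float = 0.5                  # m
    csm_percentile: float = 99.0       # percent
    max_kernel_small: float = 0.15     # m, kernel diameter
    max_kernel_large: float = 0.80     # m, kernel diameter
    diff_threshold: float = 10.0       # cm
    gaussian_sigma: float = 1.0        # cells
    min_points_per_cell: int = 1
    ground_slope_tol_cm: float = 10.0  # per-cell lowest-point tolerance
    knn: int = 8                       # neighbors for moving-planes
    search_radius: float = 2.0         # m, moving-planes neighbor cutoff

    def __post_init__(self) -> None:
        if not 0 < self.max_kernel_small < self.max_kernel_large:
            raise ValidationError("require 0 < small kernel < large kernel")
        if not 0 < self.csm_percentile <= 100:
            raise ValidationError("csm_percentile must be in (0, 100]")


def _grid_from_bounds(xmin: float, ymin: float, xmax: float, ymax: float,
                      cell: float) -> RasterGrid:
    n_cols = max(1, int(math.ceil((xmax - xmin) / cell)))
    n_rows = max(1, int(math.ceil((ymax - ymin) / cell)))
    return RasterGrid(xmin, ymin, cell, np.full((n_rows, n_cols), NODATA))


def _cell_members(cloud: PointCloud, grid: RasterGrid) -> dict[tuple[int, int], np.ndarray]:
    i, j = grid.cell_index(cloud.x, cloud.y)
    ok = (i >= 0) & (i < grid.n_rows) & (j >= 0) & (j < grid.n_cols)
    members: dict[tuple[int, int], list[int]] = {}
    for idx in np.nonzero(ok)[0]:
        members.setdefault((int(i[idx]), int(j[idx])), []).append(int(idx))
    return {k: np.asarray(v) for k, v in members.items()}


def filter_ground(cloud: PointCloud, cell: float, slope_tol_cm: float) -> PointCloud:
    """Keep, per cell, the points within ``slope_tol_cm`` of the cell minimum.

    A deliberately simple terrain filter: on an early-season scan where the
    ground dominates, off-terrain points (plants, equipment) sit well above
    the per-cell lowest return and are discarded.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot ground-filter an empty cloud")
    grid = _grid_from_bounds(cloud.x.min(), cloud.y.min(),
                             cloud.x.max() + 1e-9, cloud.y.max() + 1e-9, cell)
    i, j = grid.cell_index(cloud.x, cloud.y)
    i = np.clip(i, 0, grid.n_rows - 1)
    j = np.clip(j, 0, grid.n_cols - 1)
    flat = i * grid.n_cols + j
    order = np.argsort(flat, kind="stable")
    keep = np.zeros(len(cloud), dtype=bool)
    tol_m = slope_tol_cm / 100.0
    for group in np.split(order, np.nonzero(np.diff(flat[order]))[0] + 1):
        zmin = cloud.z[group].min()
        keep[group] = cloud.z[group] <= zmin + tol_m
    return PointCloud(cloud.xyz[keep])


def dtm_moving_planes(ground: PointCloud, params: ChmParams,
                      grid: Optional[RasterGrid] = None) -> RasterGrid:
    """Moving-planes interpolation of ground points to a raster.

    Per cell, a least-squares plane is fitted to the ``knn`` nearest ground
    points and evaluated at the cell center. Cells whose nearest neighbors
    all lie beyond ``search_radius`` (or with fewer than
    ``min_points_per_cell`` in reach) become nodata.
    """
    if len(ground) < 3:
        raise ValidationError("moving-planes interpolation needs >= 3 points")
    if grid is None:
        grid = _grid_from_bounds(ground.x.min(), ground.y.min(),
                                 ground.x.max(), ground.y.max(), params.cell)
    out = np.full((grid.n_rows, grid.n_cols), grid.nodata)
    xs, ys = grid.cell_centers()
    cx, cy = np.meshgrid(xs, ys)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    tree = cKDTree(ground.xyz[:, :2])
    k = min(params.knn, len(ground))
    dist, idx = tree.query(centers, k=k)
    dist = np.atleast_2d(dist.reshape(len(centers), -1))
    idx = np.atleast_2d(idx.reshape(len(centers), -1))
    in_reach = dist <= params.search_radius
    flat = out.ravel()
    for c in range(len(centers)):
        sel = idx[c][in_reach[c]]
        if len(sel) < params.min_points_per_cell:
            continue
        pts = ground.xyz[sel]
        if len(sel) >= 3:
            A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(sel))])
            coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
            flat[c] = coef[0] * centers[c, 0] + coef[1] * centers[c, 1] + coef[2]
        else:
            flat[c] = pts[:, 2].mean()
    return grid.copy_with(flat.reshape(out.shape))


def csm_percentile(canopy: PointCloud, params: ChmParams,
                   grid: Optional[RasterGrid] = None) -> RasterGrid:
    """Per-cell percentile of canopy elevations (linear interpolation)."""
    if len(canopy) == 0:
        raise ValidationError("empty canopy cloud")
    if grid is None:
        grid = _grid_from_bounds(canopy.x.min(), canopy.y.min(),
                                 canopy.x.max(), canopy.y.max(), params.cell)
    out = np.full((grid.n_rows, grid.n_cols), grid.nodata)
    for (i, j), members in _cell_members(canopy, grid).items():
        out[i, j] = np.percentile(canopy.z[members], params.csm_percentile)
    return grid.copy_with(out)


def chm_difference(csm: RasterGrid, dtm: RasterGrid) -> tuple[RasterGrid, int]:
    """Cellwise (CSM - DTM) * 100 -> crop height in cm.

    Nodata in either input propagates; physically impossible negative
    heights are clamped to 0 and counted.
    """
    if not csm.same_geometry(dtm):
        raise ValidationError("CSM and DTM grid geometries differ")
    valid = csm.valid & dtm.valid
    diff = np.where(valid, (csm.values - dtm.values) * 100.0, csm.nodata)
    n_clamped = int(np.sum(valid & (diff < 0)))
    diff = np.where(valid & (diff < 0), 0.0, diff)
    return csm.copy_with(diff), n_clamped


def _circle_footprint(diameter_m: float, cell: float) -> np.ndarray:
    """Kernel membership by cell-center distance <= diameter/2 (inclusive)."""
    r = diameter_m / 2.0
    n = int(math.floor(r / cell + 1e-9))
    di, dj = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    return (di * cell) ** 2 + (dj * cell) ** 2 <= r ** 2 + 1e-12


def max_filter(grid: RasterGrid, diameter: float) -> RasterGrid:
    """Local maximum over a circular kernel; nodata cells are ignored.

    A cell whose whole neighborhood is nodata stays nodata.
    """
    if diameter < grid.cell:
        raise ValidationError("kernel diameter must be >= cell size")
    footprint = _circle_footprint(diameter, grid.cell)
    work = np.where(grid.valid, grid.values, -np.inf)
    out = ndimage.maximum_filter(work, footprint=footprint, mode="constant",
                                 cval=-np.inf)
    return grid.copy_with(np.where(np.isfinite(out), out, grid.nodata))


def row_spacing_filter(chm_small: RasterGrid, chm_large: RasterGrid,
                       threshold_cm: float) -> RasterGrid:
    """Drop cells where the large-kernel maximum exceeds the small-kernel one
    by more than ``threshold_cm`` — such cells sample lower leaves between
    rows rather than plant tops."""
    if not chm_small.same_geometry(chm_large):
        raise ValidationError("grid geometries differ")
    valid = chm_small.valid & chm_large.valid
    keep = valid & ((chm_large.values - chm_small.values) <= threshold_cm)
    return chm_small.copy_with(np.where(keep, chm_small.values, chm_small.nodata))


def gaussian_seamless(grid: RasterGrid, sigma: float) -> RasterGrid:
    """Renormalized Gaussian convolution over valid cells.

    Weights are renormalized over the valid cells only, which both smooths
    and fills nodata gaps in a single pass; the kernel is truncated wide
    enough to span the grid, so any cell reachable from a valid cell is
    filled. Output values stay within [min, max] of the input (convexity of
    the normalized weights).
    """
    valid = grid.valid
    if not valid.any():
        raise ValidationError("all-nodata grid cannot be smoothed")
    truncate = max(4.0, max(grid.values.shape) / max(sigma, 1e-9))
    vals = np.where(valid, grid.values, 0.0)
    num = ndimage.gaussian_filter(vals, sigma, truncate=truncate, mode="constant")
    den = ndimage.gaussian_filter(valid.astype(float), sigma, truncate=truncate,
                                  mode="constant")
    out = np.where(den > 1e-300, num / np.maximum(den, 1e-300), grid.nodata)
    return grid.copy_with(out)


@dataclass
class ChmReport:
    """Per-stage bookkeeping of the reference-CHM derivation."""

    n_terrain_points: int
    n_ground_points: int
    n_canopy_points: int
    n_cells: int
    n_dtm_nodata: int
    n_csm_nodata: int
    n_negative_clamped: int
    n_row_filtered: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def reference_chm(terrain: PointCloud, canopy: PointCloud, params: ChmParams,
                  grid: Optional[RasterGrid] = None) -> tuple[RasterGrid, ChmReport]:
    """Full CHMREF derivation: ground filter -> DTM -> CSM -> difference ->
    small/large local-maximum filters -> row-spacing filter -> seamless
    Gaussian. Returns the CHMREF (cm) and a stage report."""
    if grid is None:
        xmin = min(terrain.x.min(), canopy.x.min())
        ymin = min(terrain.y.min(), canopy.y.min())
        xmax = max(terrain.x.max(), canopy.x.max())
        ymax = max(terrain.y.max(), canopy.y.max())
        grid = _grid_from_bounds(xmin, ymin, xmax, ymax, params.cell)
    ground = filter_ground(terrain, params.cell, params.ground_slope_tol_cm)
    dtm = dtm_moving_planes(ground, params, grid)
    csm = csm_percentile(canopy, params, grid)
    chm, n_clamped = chm_difference(csm, dtm)
    chm_small = max_filter(chm, params.max_kernel_small) \
        if params.max_kernel_small >= params.cell else chm
    chm_large = max_filter(chm_small, params.max_kernel_large)
    filtered = row_spacing_filter(chm_small, chm_large, params.diff_threshold)
    n_row_filtered = int(chm_small.valid.sum() - filtered.valid.sum())
    chmref = gaussian_seamless(filtered, params.gaussian_sigma)
    report = ChmReport(
        n_terrain_points=len(terrain),
        n_ground_points=len(ground),
        n_canopy_points=len(canopy),
        n_cells=grid.n_rows * grid.n_cols,
        n_dtm_nodata=int((~dtm.valid).sum()),
        n_csm_nodata=int((~csm.valid).sum()),
        n_negative_clamped=n_clamped,
        n_row_filtered=n_row_filtered,
    )
    return chmref, report
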