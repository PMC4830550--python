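"""Synthetic field scenes, point clouds, surveys and marker-bar photographs.

The generator emulates the study conditions this package analyses: a
150 m x 30 m maize field with crop heights between 30 and 180 cm, a ~5 m
wide buried-road strip where plants grow ~40 cm lower, four predefined
measurement rows walked by participants whose GPS fixes carry meter-scale
noise plus an unknown datum offset, and marker-bar photographs in which the
crop occludes a 200 cm bar from below. Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_io import (NODATA, MeasurementRecord, Participant, PointCloud,
                      RasterGrid, ValidationError)
from .coregistration import RowSet, SimilarityTransform
from .ps_heights import cm_to_category


@dataclass
class SceneConfig:
    """Geometry and statistics of the synthetic maize field."""

    field_length: float = 150.0     # m (x extent)
    field_width: float = 30.0       # m (y extent)
    height_min: float = 30.0        # cm
    height_max: float = 180.0       # cm
    road_center_x: float = 20.0     # m; the buried-road strip
    road_width: float = 5.0         # m
    road_depression: float = 40.0   # cm
    row_spacing: float = 0.8        # m, crop rows
    plant_spacing: float = 0.15     # m, along a crop row
    n_measurement_rows: int = 4
    cell: float = 0.5               # m, raster resolution
    correlation_length: float = 10.0  # m, height-surface smoothness
    height_noise_amplitude: float = 1.0  # 0 -> constant mid-range surface
    terrain_base: tuple[float, float] = (107.0, 109.0)  # m a.s.l., west -> east
    terrain_noise_cm: float = 3.0
    hidden_scale: float = 1.0
    hidden_rotation_max_deg: float = 2.0
    hidden_translation_max_m: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.height_min < self.height_max:
            raise ValidationError("height_min must be below height_max")
        if self.road_width <= 0 or self.field_length <= 0 or self.field_width <= 0:
            raise ValidationError("lengths must be positive")
        if not 0 <= self.road_center_x <= self.field_length:
            raise ValidationError("road_center_x outside the field")


@dataclass
class FieldScene:
    config: SceneConfig
    terrain: RasterGrid      # m a.s.l.
    true_height: RasterGrid  # cm
    rows: RowSet             # the predefined measurement rows
    hidden_offset: SimilarityTransform  # applied to simulated GPS output

    def road_mask(self) -> np.ndarray:
        """Boolean raster mask of the buried-road strip."""
        xs, _ = self.true_height.cell_centers()
        half = self.config.road_width / 2.0
        in_road = np.abs(xs - self.config.road_center_x) <= half
        return np.tile(in_road, (self.true_height.n_rows, 1))

    def empty_grid(self) -> RasterGrid:
        return self.true_height.copy_with(
            np.full_like(self.true_height.values, NODATA))


def _bilinear(grid: RasterGrid, x, y) -> np.ndarray:
    """Bilinear sample at cell-center coordinates, edge-clamped."""
    col = np.atleast_1d(np.asarray(x, dtype=float)) - grid.origin_x
    row = np.atleast_1d(np.asarray(y, dtype=float)) - grid.origin_y
    coords = np.vstack([np.clip(row / grid.cell - 0.5, 0, grid.n_rows - 1),
                        np.clip(col / grid.cell - 0.5, 0, grid.n_cols - 1)])
    return ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest")


def generate_scene(config: SceneConfig) -> FieldScene:
    """Build the deterministic synthetic field.

    The crop-height surface is band-limited noise (Gaussian-smoothed white
    noise, correlation length ``correlation_length``) rescaled into
    [height_min, height_max]; the road strip is then lowered by
    ``road_depression`` and clamped at zero. Terrain is a gentle planar
    west-east gradient plus small smooth noise.
    """
    rng = np.random.default_rng(config.seed)
    cell = config.cell
    n_cols = int(round(config.field_length / cell))
    n_rows = int(round(config.field_width / cell))

    sigma_cells = config.correlation_length / cell
    noise = rng.standard_normal((n_rows, n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma_cells, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    mid = 0.5 * (config.height_min + config.height_max)
    if hi - lo < 1e-12 or config.height_noise_amplitude == 0:
        surface = np.full((n_rows, n_cols), mid)
    else:
        scaled = config.height_min + (smooth - lo) / (hi - lo) * (
            config.height_max - config.height_min)
        surface = mid + config.height_noise_amplitude * (scaled - mid)

    height = RasterGrid(0.0, 0.0, cell, surface)
    xs, _ = height.cell_centers()
    in_road = np.abs(xs - config.road_center_x) <= config.road_width / 2.0
    surface[:, in_road] = np.maximum(surface[:, in_road] - config.road_depression, 0.0)

    z0, z1 = config.terrain_base
    terrain_vals = z0 + (z1 - z0) * (xs[None, :] - xs[0]) / max(xs[-1] - xs[0], 1e-9)
    terrain_vals = np.broadcast_to(terrain_vals, (n_rows, n_cols)).copy()
    if config.terrain_noise_cm > 0:
        tn = ndimage.gaussian_filter(rng.standard_normal((n_rows, n_cols)),
                                     sigma_cells, mode="reflect")
        span = tn.max() - tn.min()
        if span > 1e-12:
            tn = (tn - tn.min()) / span - 0.5
            terrain_vals = terrain_vals + tn * (config.terrain_noise_cm / 100.0)
    terrain = RasterGrid(0.0, 0.0, cell, terrain_vals)

    margin = 0.5
    ys = np.linspace(0, config.field_width,
                     config.n_measurement_rows + 2)[1:-1]
    rows = RowSet([np.array([[margin, y], [config.field_length - margin, y]])
                   for y in ys])

    rot = math.radians(rng.uniform(-config.hidden_rotation_max_deg,
                                   config.hidden_rotation_max_deg))
    tx = rng.uniform(-config.hidden_translation_max_m, config.hidden_translation_max_m)
    ty = rng.uniform(-config.hidden_translation_max_m, config.hidden_translation_max_m)
    hidden = SimilarityTransform(scale=config.hidden_scale, rotation=rot,
                                 tx=tx, ty=ty)
    return FieldScene(config=config, terrain=terrain, true_height=height,
                      rows=rows, hidden_offset=hidden)


def sample_point_clouds(scene: FieldScene,
                        terrain_density: float = 0.5,
                        canopy_density: float = 2.0,
                        noise_sd: float = 0.01,
                        bare_fraction: float = 0.15,
                        leaf_spread: float = 0.2,
                        seed: Optional[int] = None
                        ) -> tuple[PointCloud, PointCloud]:
    """Sample terrain and canopy scans of the scene.

    Densities are in points per 0.01 m^2 (the unit dense survey scans are
    quoted in). Canopy points sit at plant positions (crop-row /
    plant-spacing grid, jittered by ``leaf_spread`` to emulate leaves
    spanning the inter-row gap) with z drawn uniformly between 40% and 100%
    of the local crop height; a ``bare_fraction`` of ground hits between
    rows is mixed in. Gaussian vertical noise ``noise_sd`` (meters) on top.
    """
    if terrain_density <= 0 or canopy_density <= 0:
        raise ValidationError("densities must be positive")
    cfg = scene.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    area = cfg.field_length * cfg.field_width

    n_t = int(round(area * terrain_density * 100))
    tx = rng.uniform(0, cfg.field_length, n_t)
    ty = rng.uniform(0, cfg.field_width, n_t)
    tz = _bilinear(scene.terrain, tx, ty)
    if noise_sd > 0:
        tz = tz + rng.normal(0, noise_sd, n_t)
    terrain_cloud = PointCloud(np.column_stack([tx, ty, tz]))

    n_c = int(round(area * canopy_density * 100))
    n_bare = int(round(n_c * bare_fraction))
    n_plant = n_c - n_bare

    crop_rows = np.arange(cfg.row_spacing / 2, cfg.field_width, cfg.row_spacing)
    plant_x = np.arange(cfg.plant_spacing / 2, cfg.field_length, cfg.plant_spacing)
    px = plant_x[rng.integers(0, len(plant_x), n_plant)]
    py = crop_rows[rng.integers(0, len(crop_rows), n_plant)]
    if leaf_spread > 0:
        px = px + rng.normal(0, leaf_spread, n_plant)
        py = py + rng.normal(0, leaf_spread, n_plant)
    px = np.clip(px, 0, cfg.field_length - 1e-9)
    py = np.clip(py, 0, cfg.field_width - 1e-9)
    h_cm = _bilinear(scene.true_height, px, py)
    u = rng.uniform(0.4, 1.0, n_plant)
    pz = _bilinear(scene.terrain, px, py) + u * h_cm / 100.0

    bx = rng.uniform(0, cfg.field_length, n_bare)
    by = rng.uniform(0, cfg.field_width, n_bare)
    bz = _bilinear(scene.terrain, bx, by)

    cx = np.concatenate([px, bx])
    cy = np.concatenate([py, by])
    cz = np.concatenate([pz, bz])
    if noise_sd > 0:
        cz = cz + rng.normal(0, noise_sd, len(cz))
    canopy_cloud = PointCloud(np.column_stack([cx, cy, cz]))
    return terrain_cloud, canopy_cloud


def generate_participants(n: int, seed: int = 0,
                          id_offset: int = 0) -> list[Participant]:
    """Plausible body/knee heights (cm) for n participants."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        body = float(np.round(rng.uniform(155, 195)))
        knee = float(np.round(rng.uniform(42, 58)))
        out.append(Participant(participant_id=id_offset + i,
                               body_height_cm=body, knee_height_cm=knee))
    return out


def _gradient_threshold(scene: FieldScene, percentile: float = 85.0) -> float:
    gy, gx = np.gradient(scene.true_height.values, scene.true_height.cell)
    mag = np.hypot(gx, gy)
    return float(np.percentile(mag, percentile))


def simulate_survey(scene: FieldScene, participants: Sequence[Participant],
                    group: str, gps_sigma: float = 1.2,
                    step_length: float = 0.7, i2_rate: float = 1.0,
                    m2_noise_sd: float = 2.0, m1_noise_sd: float = 10.0,
                    seed: Optional[int] = None) -> list[MeasurementRecord]:
    """Simulate one group's survey.

    Participants walk their assigned measurement rows and record a position
    every tenth step (I1). Where the local height gradient at the midpoint
    between consecutive stops exceeds its own field-wide 85th percentile,
    an additional stop is inserted with probability ``i2_rate`` (I2). True
    positions are perturbed by isotropic Gaussian GPS noise and then mapped
    through the scene's hidden datum offset; M2 is the true local height
    plus noise, M1 the nearest human-figure category of a noisy height.
    """
    if not participants:
        raise ValidationError("need at least one participant")
    if gps_sigma < 0 or step_length <= 0:
        raise ValidationError("gps_sigma >= 0 and step_length > 0 required")
    cfg = scene.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    grad_thresh = _gradient_threshold(scene)
    gy_, gx_ = np.gradient(scene.true_height.values, scene.true_height.cell)
    grad_x = scene.true_height.copy_with(gx_)
    grad_y = scene.true_height.copy_with(gy_)
    spacing = 10.0 * step_length
    records: list[MeasurementRecord] = []
    rid = 0
    n_rows = len(scene.rows.polylines)

    def emit(pt_true: np.ndarray, instruction: str, p: Participant) -> None:
        nonlocal rid
        h_true = float(_bilinear(scene.true_height, pt_true[0], pt_true[1])[0])
        m2 = max(h_true + (rng.normal(0, m2_noise_sd) if m2_noise_sd > 0 else 0.0), 0.0)
        m1 = cm_to_category(h_true + (rng.normal(0, m1_noise_sd) if m1_noise_sd > 0 else 0.0), p)
        noisy = pt_true + (rng.normal(0, gps_sigma, 2) if gps_sigma > 0 else 0.0)
        gx, gy = scene.hidden_offset.apply(noisy)[0]
        records.append(MeasurementRecord(
            record_id=rid, participant_id=p.participant_id, group=group,
            instruction=instruction, x=float(gx), y=float(gy),
            m1_category=m1, m2_height_cm=float(m2)))
        rid += 1

    for k, participant in enumerate(participants):
        poly = scene.rows.polylines[k % n_rows]
        a, b = poly[0], poly[-1]
        length = float(np.hypot(*(b - a)))
        direction = (b - a) / length
        # walks start at the row's field-edge vertex and also record the far
        # end; the end stops anchor the along-row component of the datum fit
        stops = np.arange(0.0, length, spacing)
        if length - stops[-1] > 1e-9:
            stops = np.append(stops, length)
        prev_pt = None
        prev_h = None
        for s in stops:
            pt = a + s * direction
            h = float(_bilinear(scene.true_height, pt[0], pt[1])[0])
            if prev_pt is not None and i2_rate > 0:
                mid = 0.5 * (prev_pt + pt)
                # gradient magnitude at the midpoint, bilinearly sampled
                gmag = float(np.hypot(_bilinear(grad_x, mid[0], mid[1])[0],
                                      _bilinear(grad_y, mid[0], mid[1])[0]))
                if gmag > grad_thresh and rng.uniform() < i2_rate:
                    emit(mid, "I2", participant)
            emit(pt, "I1", participant)
            prev_pt, prev_h = pt, h
    return records


DEFAULT_SURVEY = {
    "GPS": dict(gps_sigma=1.2, i2_rate=1.0, m2_noise_sd=2.0, m1_noise_sd=10.0),
    "SP": dict(gps_sigma=5.0, i2_rate=1.0, m2_noise_sd=2.0, m1_noise_sd=10.0),
}


# ---------------------------------------------------------------------------
# marker-bar photograph renderer

BAR_WIDTH_CM = 6.0
REF_WIDTH_CM = 3.0

_COL_BAR = np.array([235, 235, 215], dtype=float)
_COL_REF = np.array([215, 40, 40], dtype=float)
_COL_CIRCLE = np.array([255, 0, 255], dtype=float)
_COL_CROP = np.array([60, 140, 50], dtype=float)
_COL_BG = np.array([150, 130, 95], dtype=float)


def render_marker_image(local_height: float, width_px: int = 160,
                        height_px: int = 480, ref_px_per_cm: float = 2.0,
                        clutter_level: float = 0.3, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render a marker-bar scene plus its exact ground-truth label mask.

    The 200 cm bar (with the distinct 15 cm reference band at its top) is
    occluded from the bottom up to ``local_height`` by textured green crop
    pixels; a circle stroke around the bar emulates the participant's
    touchscreen annotation. Truth-mask classes: 0 background, 1 marker bar,
    2 reference area, 3 circle. The reference band is narrower than the
    bar, so the bar's flanks remain marker-class over its full visible
    length.
    """
    if not 0 <= local_height <= 200:
        raise ValidationError("local_height must be within [0, 200] cm")
    if ref_px_per_cm <= 0:
        raise ValidationError("ref_px_per_cm must be positive")
    s = ref_px_per_cm
    bar_px = int(round(200.0 * s))
    if bar_px + 20 > height_px:
        raise ValidationError("image too short for the bar at this scale")
    rng = np.random.default_rng(seed)

    img = np.empty((height_px, width_px, 3), dtype=float)
    base_noise = ndimage.gaussian_filter(
        rng.standard_normal((height_px, width_px)), 3.0)
    img[:] = _COL_BG + (clutter_level * 120.0 * base_noise)[..., None]
    truth = np.zeros((height_px, width_px), dtype=np.int8)

    r0 = (height_px - bar_px) // 2
    r1 = r0 + bar_px  # exclusive
    cc = width_px // 2
    bw = max(1, int(round(BAR_WIDTH_CM * s)))
    rw = max(1, int(round(REF_WIDTH_CM * s)))
    bar_c0, bar_c1 = cc - bw // 2, cc - bw // 2 + bw
    ref_c0, ref_c1 = cc - rw // 2, cc - rw // 2 + rw
    ref_rows = int(round(15.0 * s))

    img[r0:r1, bar_c0:bar_c1] = _COL_BAR
    truth[r0:r1, bar_c0:bar_c1] = 1
    img[r0:r0 + ref_rows, ref_c0:ref_c1] = _COL_REF
    truth[r0:r0 + ref_rows, ref_c0:ref_c1] = 2

    # crop occlusion: everything below the visible bar bottom
    visible_px = int(round((200.0 - local_height) * s))
    occ_top = r0 + visible_px
    if occ_top < height_px:
        crop_noise = ndimage.gaussian_filter(
            rng.standard_normal((height_px - occ_top, width_px)), 2.0)
        img[occ_top:] = _COL_CROP + (35.0 * crop_noise)[..., None]
        truth[occ_top:] = 0

    # circle stroke (participant annotation), drawn on top of everything
    ry = bar_px / 2.0 + 0.04 * height_px
    rx = width_px * 0.38
    cy = r0 + bar_px / 2.0
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    q = ((xx - cc) / rx) ** 2 + ((yy - cy) / ry) ** 2
    stroke = (q >= 0.90) & (q <= 1.10)
    img[stroke] = _COL_CIRCLE
    truth[stroke] = 3

    img += rng.normal(0, 2.0, img.shape)  # sensor noise
    return np.clip(img, 0, 255).astype(np.uint8), truth


def sparse_labels(truth: np.ndarray, fraction: float = 0.02,
                  seed: int = 0) -> np.ndarray:
    """Keep a random fraction of each class's pixels labeled, -1 elsewhere.

    Emulates the sparse brush strokes of interactive labeling.
    """
    rng = np.random.default_rng(seed)
    out = np.full(truth.shape, -1, dtype=np.int16)
    for cls in np.unique(truth):
        idx = np.nonzero(truth.ravel() == cls)[0]
        n = max(1, int(round(len(idx) * fraction)))
        pick = rng.choice(idx, size=min(n, len(idx)), replace=False)
        out.ravel()[pick] = cls
    return out
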