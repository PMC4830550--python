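"""Evaluation statistics and the end-to-end synthetic pipeline.

Agreement between the participatory crop-height surface (CHMPS) and the
laser-scanning reference (CHMREF) is scored the way field comparisons of
crop-height models usually are: squared Pearson correlation after dropping
pairs whose absolute height difference exceeds the 95th percentile
(Pearson is not robust to outliers), plus RMSE / mean / SD of the
difference raster, overall and over the buried-road strip, with and
without the participant-judged additional measurements (I2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import ps_heights
from .core_io import RasterGrid, ValidationError
from .coregistration import fit_similarity, rmse_to_rows
from .interpolation import empirical_semivariogram, fit_variogram, ordinary_krige
from .synthetic_data import (DEFAULT_SURVEY, FieldScene, SceneConfig,
                             generate_participants, generate_scene,
                             sample_point_clouds, simulate_survey)
from .tls_chm import ChmParams, reference_chm

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

# Field-campaign tallies from the published survey overview (counts of
# direct measurements per sensor group and instruction regime).
CAMPAIGN_COUNTS = {
    "GPS": {"total": 273, "I1": 226, "I2": 47},
    "SP": {"total": 357, "I1": 253, "I2": 104},
}


def instruction_shares(counts: dict[str, int]) -> dict[str, float]:
    """I1/I2 percentage shares from a {total, I1, I2} count row."""
    total = counts["I1"] + counts["I2"]
    if total != counts["total"]:
        raise ValidationError("I1 + I2 must equal the total count")
    return {"I1_pct": 100.0 * counts["I1"] / total,
            "I2_pct": 100.0 * counts["I2"] / total}


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def precision_recall(pred_mask: np.ndarray, truth_mask: np.ndarray
                     ) -> tuple[Optional[float], Optional[float], ConfusionCounts]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); undefined denominators
    are reported as None, never as 0."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    p = tp / (tp + fp) if (tp + fp) > 0 else None
    r = tp / (tp + fn) if (tp + fn) > 0 else None
    return p, r, ConfusionCounts(tp, fp, fn, tn)


def exclude_outliers_p95(pairs: np.ndarray, min_n: int = 20
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Drop pairs whose absolute difference is strictly above the 95th
    percentile of all absolute differences (linear-interpolation
    percentile). Below ``min_n`` pairs nothing is excluded, logged."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) < min_n:
        logger.info("only %d pairs (< %d): outlier exclusion skipped", len(arr), min_n)
        return arr, np.zeros(len(arr), dtype=bool)
    diffs = np.abs(arr[:, 0] - arr[:, 1])
    p95 = np.percentile(diffs, 95)
    excluded = diffs > p95
    return arr[~excluded], excluded


def r_squared(pairs: np.ndarray) -> float:
    """Squared Pearson correlation of the paired values."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) < 3:
        raise ValidationError("R^2 needs >= 3 pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("R^2 undefined for zero-variance input")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class DiffStats:
    """Statistics of a (reference - participatory) difference raster, cm.

    Positive mean = the participatory surface underestimates. ``sd`` is the
    population standard deviation by default so rmse^2 = mean^2 + sd^2
    holds exactly; sample sd is a flag away.
    """

    rmse: float
    mean: float
    sd: float
    min: float
    max: float
    n: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def diff_stats(ref: RasterGrid, ps: RasterGrid,
               mask: Optional[np.ndarray] = None,
               population_sd: bool = True) -> DiffStats:
    """Statistics of (ref - ps) over jointly valid (optionally masked) cells."""
    if not ref.same_geometry(ps):
        raise ValidationError("grid geometries differ")
    valid = ref.valid & ps.valid
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n < 1:
        raise ValidationError("no jointly valid cells to compare")
    d = (ref.values - ps.values)[valid]
    ddof = 0 if population_sd else 1
    return DiffStats(
        rmse=float(np.sqrt(np.mean(d ** 2))),
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=ddof)) if n > ddof else 0.0,
        min=float(np.min(d)),
        max=float(np.max(d)),
        n=n,
        n_excluded=int(ref.values.size - n),
    )


def estimate_road_depression(grid: RasterGrid, scene: FieldScene,
                             edge_margin_m: float = 1.0,
                             flank_width_m: float = 7.5) -> float:
    """Depression (cm, positive = lower) of the buried-road strip.

    The smooth in-field height pattern is removed by fitting, per raster
    row, a quadratic trend in x to the off-road flanks on both sides of the
    strip and predicting the strip cells from it; the depression is the
    mean of (predicted - observed) over the strip's core cells
    (``edge_margin_m`` trimmed off each side to avoid smoothing-blurred
    edges).
    """
    cfg = scene.config
    xs, _ = grid.cell_centers()
    half = cfg.road_width / 2.0
    dx = np.abs(xs - cfg.road_center_x)
    core = dx <= half - edge_margin_m
    flank = (dx > half + edge_margin_m) & (dx <= half + edge_margin_m + flank_width_m)
    if not (core.any() and flank.any()):
        raise ValidationError("road strip or flanks outside the grid")
    xf = xs[flank] - cfg.road_center_x
    xc = xs[core] - cfg.road_center_x
    deps = []
    for i in range(grid.n_rows):
        coefs = np.polyfit(xf, grid.values[i, flank], 2)
        deps.append(np.polyval(coefs, xc) - grid.values[i, core])
    return float(np.mean(deps))


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic run."""

    seed: int = 0
    scene: SceneConfig = None  # derived from seed when omitted
    chm: ChmParams = field(default_factory=ChmParams)
    terrain_density: float = 0.5   # pts per 0.01 m^2
    canopy_density: float = 2.0
    cloud_noise_sd: float = 0.01   # m
    n_participants: int = 6
    groups: tuple[str, ...] = ("GPS", "SP")
    survey_overrides: dict = field(default_factory=dict)
    variogram_family: str = "exponential"
    max_neighbors: int = 32
    n_lags: int = 15
    max_lag: float = 75.0

    def __post_init__(self) -> None:
        if self.scene is None:
            self.scene = SceneConfig(seed=self.seed)


def _survey_params(config: PipelineConfig, group: str) -> dict:
    params = dict(DEFAULT_SURVEY[group])
    params.update(config.survey_overrides.get(group, {}))
    return params


def _krige_records(records, scene: FieldScene, transform, config: PipelineConfig
                   ) -> RasterGrid:
    pts = transform.apply(np.array([[r.x, r.y] for r in records]))
    vals = np.array([r.m2_height_cm for r in records])
    emp = empirical_semivariogram(pts, vals, n_lags=config.n_lags,
                                  max_dist=config.max_lag)
    model = fit_variogram(emp, config.variogram_family)
    pred, _ = ordinary_krige(pts, vals, model, scene.empty_grid(),
                             max_neighbors=config.max_neighbors)
    return pred


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> reference CHM -> co-register -> summarize -> krige ->
    evaluate; returns the (JSON-serializable, deterministic) report."""
    scene = generate_scene(config.scene)
    logger.info("scene generated (seed %d)", config.scene.seed)

    terrain_cloud, canopy_cloud = sample_point_clouds(
        scene, config.terrain_density, config.canopy_density,
        config.cloud_noise_sd, seed=config.seed + 1)
    chmref, chm_report = reference_chm(terrain_cloud, canopy_cloud, config.chm,
                                       grid=scene.empty_grid())
    logger.info("CHMREF derived: %s", chm_report.to_dict())

    interior = np.zeros(chmref.values.shape, dtype=bool)
    interior[1:-1, 1:-1] = True
    truth_stats = diff_stats(scene.true_height, chmref, mask=interior)

    road = scene.road_mask()
    road_depression_cm = estimate_road_depression(chmref, scene)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "campaign_shares": {g: instruction_shares(c)
                            for g, c in CAMPAIGN_COUNTS.items()},
        "chm": {
            "stage_report": chm_report.to_dict(),
            "truth_rmse_cm": truth_stats.rmse,
            "truth_mean_cm": truth_stats.mean,
            "road_depression_cm": road_depression_cm,
        },
        "groups": {},
    }

    for gi, group in enumerate(config.groups):
        params = _survey_params(config, group)
        participants = generate_participants(
            config.n_participants, seed=config.seed + 10 + gi,
            id_offset=100 * gi)
        records = simulate_survey(scene, participants, group,
                                  seed=config.seed + 20 + gi, **params)
        summary = ps_heights.group_summary(
            records, {p.participant_id: p for p in participants})

        pts = np.array([[r.x, r.y] for r in records])
        fit = fit_similarity(pts, scene.rows)
        adjusted = fit.transform.apply(pts)

        ref_at = chmref.sample(adjusted[:, 0], adjusted[:, 1])
        m2 = np.array([r.m2_height_cm for r in records])
        ok = np.isfinite(ref_at)
        kept, excluded = exclude_outliers_p95(
            np.column_stack([m2[ok], ref_at[ok]]))
        r2 = r_squared(kept)

        i1_records = [r for r in records if r.instruction == "I1"]
        chmps_i1 = _krige_records(i1_records, scene, fit.transform, config)
        chmps_all = _krige_records(records, scene, fit.transform, config)

        group_report = {
            "summary": summary.to_dict(),
            "coregistration": {
                "scale": fit.transform.scale,
                "rotation_deg": float(np.degrees(fit.transform.rotation)),
                "tx": fit.transform.tx,
                "ty": fit.transform.ty,
                "rmse_before_m": fit.rmse_before,
                "rmse_after_m": fit.rmse_after,
                "n_iter": fit.n_iter,
            },
            "r2": r2,
            "n_outliers_excluded": int(excluded.sum()),
            "diff_stats": {},
        }
        for label, chmps in (("I1", chmps_i1), ("I1+I2", chmps_all)):
            group_report["diff_stats"][label] = {
                "study_area": diff_stats(chmref, chmps).to_dict(),
                "road_strip": diff_stats(chmref, chmps, mask=road).to_dict(),
            }
        report["groups"][group] = group_report
        logger.info("group %s: R^2=%.3f row-RMSE %.2f m -> %.2f m",
                    group, r2, fit.rmse_before, fit.rmse_after)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
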