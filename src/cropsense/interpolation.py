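"""Spatial interpolation of point crop heights to an area-wide raster (CHMPS).

Ordinary kriging with a weighted-least-squares-fitted variogram. The
variogram families use the "effective range" convention: at lag = range the
exponential model has reached 95% of its sill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core_io import RasterGrid, ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("exponential", "spherical")


@dataclass
class VariogramModel:
    """Semivariance as a function of lag distance.

    nugget and partial_sill in value units squared (cm^2 for crop heights);
    range in meters (effective range).
    """

    family: str
    nugget: float
    partial_sill: float
    range: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range <= 0:
            raise ValidationError("variogram parameters must be non-negative, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / self.range)
        else:  # spherical
            hr = np.minimum(h / self.range, 1.0)
            struct = 1.5 * hr - 0.5 * hr ** 3
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h > 0, gamma, 0.0)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def empirical_semivariogram(points: np.ndarray, values: np.ndarray,
                            n_lags: int = 15, max_dist: float | None = None
                            ) -> list[tuple[float, float, int]]:
    """Binned empirical semivariogram.

    gamma(h) = mean of 0.5 * (v_i - v_j)^2 over point pairs whose distance
    falls in the bin; bins with no pairs are omitted.
    Returns (lag_center, semivariance, n_pairs) tuples.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValidationError("semivariogram needs >= 2 points")
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(pts[iu, 0] - pts[ju, 0], pts[iu, 1] - pts[ju, 1])
    sq = 0.5 * (vals[iu] - vals[ju]) ** 2
    if max_dist is None:
        max_dist = float(d.max())
    if not max_dist > 0:
        raise ValidationError("max_dist must be positive")
    edges = np.linspace(0, max_dist, n_lags + 1)
    which = np.digitize(d, edges) - 1
    out = []
    for b in range(n_lags):
        sel = which == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        out.append((float(0.5 * (edges[b] + edges[b + 1])),
                    float(sq[sel].mean()), cnt))
    return out


def fit_variogram(empirical: Sequence[tuple[float, float, int]],
                  family: str = "exponential") -> VariogramModel:
    """WLS fit (weights = pair counts) of a variogram model to binned data."""
    if len(empirical) < 3:
        raise ValidationError("variogram fit needs >= 3 bins")
    lags = np.array([e[0] for e in empirical])
    gammas = np.array([e[1] for e in empirical])
    counts = np.array([e[2] for e in empirical], dtype=float)
    w = np.sqrt(counts)

    sill0 = max(float(gammas.mean()), 1e-12)
    range0 = max(float(lags.max()) / 2.0, 1e-6)
    x0 = np.array([0.1 * sill0, 0.9 * sill0, range0])

    def resid(theta):
        model = VariogramModel(family, max(theta[0], 0.0),
                               max(theta[1], 0.0), max(theta[2], 1e-12))
        return w * (model(lags) - gammas)

    sol = least_squares(resid, x0, bounds=([0, 0, 1e-9],
                                           [np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"variogram fit failed: {sol.message}")
    nugget, psill, rng = sol.x
    # pure-nugget data can push the structured part to ~0; keep range sane
    return VariogramModel(family, float(nugget), float(psill), float(max(rng, 1e-9)))


def _dedupe(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if len(uniq) == len(pts):
        return pts, vals
    sums = np.zeros(len(uniq))
    cnts = np.zeros(len(uniq))
    np.add.at(sums, inverse, vals)
    np.add.at(cnts, inverse, 1)
    return uniq, sums / cnts


def ordinary_krige(points: np.ndarray, values: np.ndarray, model: VariogramModel,
                   grid_spec: RasterGrid, max_neighbors: int = 32
                   ) -> tuple[RasterGrid, RasterGrid]:
    """Ordinary kriging of point values onto ``grid_spec``'s geometry.

    Per cell the kriging system is solved over the ``max_neighbors``
    nearest points (semivariance formulation with a Lagrange multiplier, so
    weights sum to 1). Returns prediction and kriging-variance rasters.
    Duplicate coordinates are averaged beforehand; near-singular systems
    get 1e-8 added to the diagonal, logged.
    """
    pts, vals = _dedupe(points, values)
    if len(pts) < 2:
        raise ValidationError("kriging needs >= 2 non-coincident points")
    tree = cKDTree(pts)
    xs, ys = grid_spec.cell_centers()
    cx, cy = np.meshgrid(xs, ys)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    k = min(max_neighbors, len(pts))
    dist, idx = tree.query(centers, k=k)
    dist = dist.reshape(len(centers), k)
    idx = idx.reshape(len(centers), k)

    pred = np.empty(len(centers))
    var = np.empty(len(centers))
    n_jittered = 0
    # cache per unique neighbor set: the factorized LHS
    for c in range(len(centers)):
        nb = idx[c]
        P = pts[nb]
        g0 = model(dist[c])
        D = np.hypot(P[:, 0, None] - P[None, :, 0], P[:, 1, None] - P[None, :, 1])
        K = np.empty((k + 1, k + 1))
        K[:k, :k] = model(D)
        K[k, :] = 1.0
        K[:, k] = 1.0
        K[k, k] = 0.0
        rhs = np.append(g0, 1.0)
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            K[np.diag_indices(k)] += 1e-8
            sol = np.linalg.solve(K, rhs)
            n_jittered += 1
        lam, mu = sol[:k], sol[k]
        pred[c] = lam @ vals[nb]
        var[c] = max(lam @ g0 + mu, 0.0)
    if n_jittered:
        logger.warning("kriging: %d near-singular systems stabilized with 1e-8 jitter",
                       n_jittered)
    shape = (grid_spec.n_rows, grid_spec.n_cols)
    return (grid_spec.copy_with(pred.reshape(shape)),
            grid_spec.copy_with(var.reshape(shape)))


def krige_weights(target: np.ndarray, points: np.ndarray,
                  model: VariogramModel) -> tuple[np.ndarray, float]:
    """Solve one ordinary-kriging system explicitly (weights, Lagrange mu).

    Exposed for diagnostics and tests of the unit-sum constraint.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    t = np.asarray(target, dtype=float)
    n = len(pts)
    D = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = model(D)
    K[n, :] = 1.0
    K[:, n] = 1.0
    K[n, n] = 0.0
    g0 = model(np.hypot(pts[:, 0] - t[0], pts[:, 1] - t[1]))
    sol = np.linalg.solve(K, np.append(g0, 1.0))
    return sol[:n], float(sol[n])
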