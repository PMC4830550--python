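"""Co-registration of GPS measurement positions onto the reference rows.

Handheld-GPS positions carry meter-scale error and an unknown datum offset
relative to the laser-scanned reference frame, but the participants walked
along known, surveyed measurement rows. The positions are therefore aligned
to the row geometry with a 2-D similarity transform (uniform scale, rotation,
translation — shape-preserving, no skew), fitted by an iterative
closest-point scheme: project the transformed points onto the rows, solve
the closed-form least-squares similarity (Procrustes with isotropic scale)
against those projections, repeat until the row RMSE stops improving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import ValidationError


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = scale * R(rotation) @ p + (tx, ty)."""

    scale: float = 1.0
    rotation: float = 0.0  # radians, counter-clockwise
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("similarity scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = -self.tx, -self.ty
        return SimilarityTransform(
            scale=inv_scale,
            rotation=-self.rotation,
            tx=inv_scale * (c * tx - s * ty),
            ty=inv_scale * (s * tx + c * ty),
        )

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ inner (apply ``inner`` first)."""
        m = self.matrix @ np.array([inner.tx, inner.ty]) + np.array([self.tx, self.ty])
        return SimilarityTransform(
            scale=self.scale * inner.scale,
            rotation=self.rotation + inner.rotation,
            tx=float(m[0]),
            ty=float(m[1]),
        )


@dataclass
class RowSet:
    """The predefined measurement rows as polylines of (x, y) vertices."""

    polylines: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polylines]
        if not self.polylines:
            raise ValidationError("RowSet needs at least one polyline")
        for p in self.polylines:
            if p.shape[0] < 2:
                raise ValidationError("each polyline needs >= 2 vertices")

    def segments(self) -> np.ndarray:
        """All segments as an (m, 2, 2) array, in polyline-then-segment order."""
        segs = []
        for poly in self.polylines:
            for a, b in zip(poly[:-1], poly[1:]):
                segs.append((a, b))
        return np.asarray(segs)


def write_rows(rows: RowSet, path) -> None:
    """Blank-line-separated polylines, one 'x y' vertex per line."""
    with open(path, "w") as fh:
        for k, poly in enumerate(rows.polylines):
            if k:
                fh.write("\n")
            for x, y in poly:
                fh.write(f"{float(x)!r} {float(y)!r}\n")


def read_rows(path) -> RowSet:
    polylines: list[list[list[float]]] = [[]]
    for line in open(path):
        line = line.strip()
        if not line:
            if polylines[-1]:
                polylines.append([])
            continue
        x, y = line.split()[:2]
        polylines[-1].append([float(x), float(y)])
    return RowSet([p for p in polylines if p])


def _project_onto_segments(points: np.ndarray, segs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on any segment for each input point.

    Ties are broken by segment order (first polyline, then first segment)
    via a strict less-than comparison.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    a = segs[:, 0]  # (m, 2)
    b = segs[:, 1]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)  # (m,)
    denom = np.where(denom == 0, 1.0, denom)
    # t for every (point, segment) pair, clamped to the segment
    ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]  # (n, m, 2)
    d2 = np.sum((pts[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)  # argmin returns the first minimum
    idx = np.arange(pts.shape[0])
    return proj[idx, best], np.sqrt(d2[idx, best])


def nearest_on_rows(point: Sequence[float], rows: RowSet) -> tuple[np.ndarray, float]:
    """Closest point on the rows and its distance, for a single point."""
    proj, dist = _project_onto_segments(np.asarray(point, dtype=float), rows.segments())
    return proj[0], float(dist[0])


def rmse_to_rows(points: np.ndarray, rows: RowSet) -> float:
    """Root mean squared nearest-row distance (meters)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValidationError("need at least one point")
    _, dist = _project_onto_segments(pts, rows.segments())
    return float(np.sqrt(np.mean(dist ** 2)))


def _solve_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity mapping src onto dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    s0 = src - cs
    d0 = dst - cd
    denom = float(np.sum(s0 ** 2))
    if denom <= 1e-300:
        raise ValidationError("degenerate point set: all points coincide")
    a = float(np.sum(s0 * d0))                       # sum of dot products
    b = float(np.sum(s0[:, 0] * d0[:, 1] - s0[:, 1] * d0[:, 0]))  # cross terms
    rotation = math.atan2(b, a)
    scale = math.hypot(a, b) / denom
    if scale <= 0:
        scale = 1.0
    c, s = math.cos(rotation), math.sin(rotation)
    tx = cd[0] - scale * (c * cs[0] - s * cs[1])
    ty = cd[1] - scale * (s * cs[0] + c * cs[1])
    return SimilarityTransform(scale=scale, rotation=rotation, tx=tx, ty=ty)


def _solve_similarity_fixed_assignment(pts: np.ndarray, segs: np.ndarray,
                                       transform: SimilarityTransform
                                       ) -> SimilarityTransform:
    """Exact minimizer of the fixed-assignment objective.

    Given the current transform's nearest-segment assignments, the distance
    of each point is to its segment's infinite line (interior projections)
    or to the clamped end vertex. Both are linear in the parametrization
    (a, b, tx, ty) with sR = [[a, -b], [b, a]], so one least-squares solve
    minimizes the assignment-frozen objective exactly — a Gauss-Newton step
    that removes the tangential crawl of plain projection ICP.
    """
    current = transform.apply(pts)
    a_seg = segs[:, 0]
    ab = segs[:, 1] - segs[:, 0]
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = current[:, None, :] - a_seg[None, :, :]
    t = np.einsum("nmj,mj->nm", ap, ab) / denom[None, :]
    t_cl = np.clip(t, 0.0, 1.0)
    proj = a_seg[None, :, :] + t_cl[..., None] * ab[None, :, :]
    d2 = np.sum((current[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    n_pts = pts.shape[0]
    rows_A: list[np.ndarray] = []
    rows_b: list[float] = []
    for i in range(n_pts):
        m = best[i]
        px, py = pts[i]
        ti = t[i, m]
        if 0.0 < ti < 1.0:
            seg_dir = ab[m] / math.sqrt(denom[m])
            nx, ny = -seg_dir[1], seg_dir[0]
            ax, ay = a_seg[m]
            rows_A.append([nx * px + ny * py, -nx * py + ny * px, nx, ny])
            rows_b.append(nx * ax + ny * ay)
        else:
            vx, vy = segs[m, 0] if ti <= 0 else segs[m, 1]
            rows_A.append([px, -py, 1.0, 0.0])
            rows_b.append(vx)
            rows_A.append([py, px, 0.0, 1.0])
            rows_b.append(vy)
    A = np.asarray(rows_A)
    b = np.asarray(rows_b)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    al, be, tx, ty = sol
    scale = math.hypot(al, be)
    if scale <= 1e-12:
        raise ValidationError("degenerate fixed-assignment solve")
    return SimilarityTransform(scale=scale, rotation=math.atan2(be, al),
                               tx=float(tx), ty=float(ty))


@dataclass
class FitResult:
    transform: SimilarityTransform
    rmse_before: float
    rmse_after: float
    n_iter: int
    rmse_history: list[float] = field(default_factory=list)


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    return math.remainder(theta, 2.0 * math.pi)


def _principal_angle(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    return math.atan2(v[1], v[0])


def _initial_transforms(pts: np.ndarray, rows: RowSet,
                        scale_bounds: tuple[float, float] = (0.8, 1.25)
                        ) -> list[SimilarityTransform]:
    """Candidate ICP starts: identity plus a centroid/principal-axis
    alignment (and small cross-row shifts of it, to escape wrong nearest-row
    assignments)."""
    candidates = [SimilarityTransform()]
    verts = np.vstack(rows.polylines)
    segs = rows.segments()
    lengths = np.hypot(*(segs[:, 1] - segs[:, 0]).T)
    dirs = segs[:, 1] - segs[:, 0]
    # length-weighted mean row direction (sign-folded into a half circle)
    angles = np.arctan2(dirs[:, 1], dirs[:, 0]) % math.pi
    beta = float(np.angle(np.sum(lengths * np.exp(2j * angles))) / 2.0)
    alpha = _principal_angle(pts)
    for rot in (beta - alpha, beta - alpha + math.pi):
        c, s = math.cos(rot), math.sin(rot)
        rotated = pts @ np.array([[c, -s], [s, c]]).T
        span_pts = np.ptp(rotated @ np.array([math.cos(beta), math.sin(beta)]))
        span_rows = np.ptp(verts @ np.array([math.cos(beta), math.sin(beta)]))
        scale = span_rows / span_pts if span_pts > 1e-9 else 1.0
        scale = min(max(scale, scale_bounds[0]), scale_bounds[1])
        base_t = verts.mean(axis=0) - scale * rotated.mean(axis=0)
        normal = np.array([-math.sin(beta), math.cos(beta)])
        for shift in (0.0, -2.0, 2.0):
            t = base_t + shift * normal
            candidates.append(SimilarityTransform(scale=scale, rotation=rot,
                                                  tx=float(t[0]), ty=float(t[1])))
    return candidates


def fit_similarity(points: np.ndarray, rows: RowSet,
                   max_iter: int = 100, tol: float = 1e-6,
                   scale_bounds: tuple[float, float] = (0.8, 1.25),
                   max_rotation: float = math.radians(45.0)) -> FitResult:
    """ICP fit of a similarity transform taking ``points`` onto ``rows``.

    Each iteration projects the currently transformed points onto the rows
    and solves the closed-form similarity against the projections; within a
    run the row RMSE is non-increasing and iteration stops once the
    improvement falls below ``tol`` (meters). Because nearest-row
    assignment makes the objective multimodal, several initializations
    (identity plus centroid/principal-axis alignments) are tried and the
    best final fit returned.

    ``scale_bounds`` and ``max_rotation`` guard against degenerate or
    symmetry-flipped attractors of row-distance minimization (shrinking the
    survey onto the rows, or mapping a symmetric row pattern onto itself
    upside down): GPS datum errors in scale and orientation are tiny, so
    candidate steps outside the bands are rejected.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValidationError("similarity fit needs >= 3 points")
    if np.allclose(pts, pts[0]):
        raise ValidationError("degenerate point set: all points coincide")
    segs = rows.segments()
    rmse_before = rmse_to_rows(pts, rows)

    best: FitResult | None = None
    inits = [t for t in _initial_transforms(pts, rows, scale_bounds)
             if abs(_wrap_angle(t.rotation)) <= max_rotation]
    if not inits:
        inits = [SimilarityTransform()]
    for init in inits:
        transform = init
        history = [rmse_to_rows(transform.apply(pts), rows)]
        for _ in range(max_iter):
            proj, _ = _project_onto_segments(transform.apply(pts), segs)
            try:
                cand_proj = _solve_similarity(pts, proj)
            except ValidationError:
                break
            candidates = [cand_proj]
            try:
                candidates.append(
                    _solve_similarity_fixed_assignment(pts, segs, transform))
            except (ValidationError, np.linalg.LinAlgError):
                pass
            candidates = [
                c for c in candidates
                if scale_bounds[0] <= c.scale <= scale_bounds[1]
                and abs(_wrap_angle(c.rotation)) <= max_rotation]
            if not candidates:
                break
            # the projection step is guaranteed non-increasing; the exact
            # fixed-assignment step usually converges far faster — keep
            # whichever ends lower, so the history stays monotone
            scored = [(rmse_to_rows(c.apply(pts), rows), c) for c in candidates]
            rmse, transform = min(scored, key=lambda sc: sc[0])
            if rmse > history[-1]:
                break
            history.append(rmse)
            if history[-2] - rmse < tol:
                break
        result = FitResult(transform=transform, rmse_before=rmse_before,
                           rmse_after=history[-1], n_iter=len(history) - 1,
                           rmse_history=history)
        if best is None or result.rmse_after < best.rmse_after:
            best = result
    return best


def fit_similarity_per_row(points: np.ndarray, rows: RowSet,
                           max_iter: int = 100, tol: float = 1e-6
                           ) -> list[tuple[np.ndarray, FitResult]]:
    """Co-register each row's points separately.

    Points are assigned to their nearest polyline and each subset is fitted
    onto its own row; returns (point indices, fit) per row that received at
    least three points. Useful when each row was surveyed independently.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    dists = np.empty((pts.shape[0], len(rows.polylines)))
    for k, poly in enumerate(rows.polylines):
        single = RowSet([poly])
        _, d = _project_onto_segments(pts, single.segments())
        dists[:, k] = d
    assignment = np.argmin(dists, axis=1)
    out = []
    for k, poly in enumerate(rows.polylines):
        idx = np.nonzero(assignment == k)[0]
        if len(idx) < 3:
            continue
        fit = fit_similarity(pts[idx], RowSet([poly]), max_iter=max_iter, tol=tol)
        out.append((idx, fit))
    return out
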