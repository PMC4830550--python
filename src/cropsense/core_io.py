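"""Shared domain types and plain-text readers/writers.

Conventions used throughout the package:

* planar coordinates in meters; point-cloud and elevation-raster z in meters
  above sea level; crop heights in centimeters
* rasters use a lower-left origin; ``values[0, :]`` is the southernmost row
  and the center of cell (i, j) is at ``origin + ((j + 0.5) * cell,
  (i + 0.5) * cell)``
* nodata sentinel defaults to -9999.0 (ESRI ASCII convention)
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NODATA = -9999.0

EARTH_RADIUS_M = 6371000.0


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed values violate domain constraints."""


@dataclass(frozen=True)
class PointCloud:
    """Unordered x, y, z records (meters)."""

    xyz: np.ndarray  # (n, 3) float array

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "xyz", arr)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


@dataclass
class RasterGrid:
    """Georeferenced 2-D value array with a lower-left origin.

    Row 0 is the *southernmost* row; ``write_ascii_grid`` flips to the
    north-to-south order that the ESRI ASCII dialect requires.
    """

    origin_x: float
    origin_y: float
    cell: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be 2-D")
        if not self.cell > 0:
            raise ValidationError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells holding data."""
        return self.values != self.nodata

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) of cell centers; xs has length n_cols, ys n_rows."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell
        return xs, ys

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing (x, y); no bounds check."""
        j = np.floor((np.asarray(x) - self.origin_x) / self.cell).astype(int)
        i = np.floor((np.asarray(y) - self.origin_y) / self.cell).astype(int)
        return i, j

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup; nodata/out-of-bounds return NaN."""
        i, j = self.cell_index(x, y)
        out = np.full(np.shape(i), np.nan, dtype=float)
        ok = (i >= 0) & (i < self.n_rows) & (j >= 0) & (j < self.n_cols)
        vals = self.values[i[ok], j[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_x, self.origin_y, self.cell,
                          np.asarray(values, dtype=float), self.nodata)


@dataclass(frozen=True)
class Participant:
    participant_id: int
    body_height_cm: float
    knee_height_cm: float

    def __post_init__(self) -> None:
        if not (140 <= self.body_height_cm <= 210):
            raise ValidationError("body height outside plausible 140-210 cm range")
        if not (35 <= self.knee_height_cm <= 70):
            raise ValidationError("knee height outside plausible 35-70 cm range")
        if not self.knee_height_cm < self.body_height_cm:
            raise ValidationError("knee height must be below body height")


@dataclass
class MeasurementRecord:
    """One participant observation: position, instruction regime, and the
    category-based (M1) and ruler (M2) crop heights."""

    record_id: int
    participant_id: int
    group: str  # "GPS" or "SP"
    instruction: str  # "I1" or "I2"
    lat: float | None = None
    lon: float | None = None
    x: float | None = None  # local meters, once projected / simulated
    y: float | None = None
    m1_category: int | None = None
    m2_height_cm: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("GPS", "SP"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.instruction not in ("I1", "I2"):
            raise ValidationError(f"instruction must be I1 or I2, got {self.instruction!r}")
        if self.m1_category is not None and not (1 <= self.m1_category <= 10):
            raise ValidationError(f"M1 category {self.m1_category} outside 1-10")
        if self.m2_height_cm is not None and self.m2_height_cm < 0:
            raise ValidationError("M2 height must be non-negative")


def read_xyz(path: str | Path) -> PointCloud:
    """Read a whitespace- or comma-delimited XYZ text point cloud.

    Lines starting with ``#`` are comments; the first three numeric columns
    are x, y, z and any further columns are ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >=3 columns, got {len(parts)}")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed numeric field ({exc})") from None
    if not rows:
        warnings.warn(f"{path}: no data lines, returning empty point cloud")
        return PointCloud(np.empty((0, 3)))
    return PointCloud(np.array(rows, dtype=float))


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    np.savetxt(path, cloud.xyz, fmt="%.6f")


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (rows north-to-south)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.origin_x)!r}\n")
        fh.write(f"yllcorner {float(grid.origin_y)!r}\n")
        fh.write(f"cellsize {float(grid.cell)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"]
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"malformed header line {line!r}")
            header[parts[0].lower()] = float(parts[1])
        for key in expected:
            if key not in header:
                raise FormatError(f"missing header keyword {key!r}")
        n_rows = int(header["nrows"])
        n_cols = int(header["ncols"])
        body = np.loadtxt(fh, dtype=float, ndmin=2)
        if body.shape != (n_rows, n_cols):
            raise FormatError(
                f"grid body shape {body.shape} != header ({n_rows}, {n_cols})")
    return RasterGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell=header["cellsize"],
        values=body[::-1].copy(),
        nodata=header["nodata_value"],
    )


def latlon_to_local(lat: np.ndarray, lon: np.ndarray,
                    lat0: float | None = None,
                    lon0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection about the centroid of the input points.

    Adequate for fields a few hundred meters across, where the planar
    distortion is far below GPS noise.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat0 is None:
        lat0 = float(np.mean(lat))
    if lon0 is None:
        lon0 = float(np.mean(lon))
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * math.cos(math.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


_COLUMN_TOKENS = {
    "lat": "lat",
    "lon": "lon",
    "instruction": "instruction",
    "m1": "m1",
    "m2": "m2",
}


def _match_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        low = col.lower().strip()
        for token, key in _COLUMN_TOKENS.items():
            if token in low and key not in mapping:
                mapping[key] = col
        # local planar coordinates: exact single-letter columns
        if low == "x" and "x" not in mapping:
            mapping["x"] = col
        if low == "y" and "y" not in mapping:
            mapping["y"] = col
    return mapping


def _sniff_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in (";", ",", "\t")}
    return max(counts, key=counts.get) if max(counts.values()) else ";"


def read_measurements(path: str | Path, group: str) -> list[MeasurementRecord]:
    """Read a participant measurement table in the survey-CSV dialect.

    The dialect: a delimited header row (``;``, ``,`` or tab) with columns
    recognisable, case-insensitively, by the tokens "lat", "lon",
    "instruction", "M1" and "M2"; one observation per row; empty M1/M2 cells
    mean "not recorded".
    """
    text = Path(path).read_text()
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str, skipinitialspace=True)
    mapping = _match_columns(df.columns)
    has_latlon = "lat" in mapping and "lon" in mapping
    has_xy = "x" in mapping and "y" in mapping
    if not (has_latlon or has_xy):
        raise FormatError(
            f"no recognizable coordinate columns among {list(df.columns)}")

    records: list[MeasurementRecord] = []
    bad_m1: list[int] = []
    for idx, row in df.iterrows():
        instruction = str(row[mapping["instruction"]]).strip() if "instruction" in mapping else "I1"
        m1 = None
        if "m1" in mapping:
            cell = row[mapping["m1"]]
            if pd.notna(cell) and str(cell).strip():
                m1 = int(float(str(cell).strip()))
                if not (1 <= m1 <= 10):
                    bad_m1.append(int(idx) + 2)  # 1-based line number incl. header
        m2 = None
        if "m2" in mapping:
            cell = row[mapping["m2"]]
            if pd.notna(cell) and str(cell).strip():
                m2 = float(str(cell).strip())
        if bad_m1:
            continue

        def _num(key: str) -> float | None:
            cell = row[mapping[key]]
            if pd.isna(cell) or not str(cell).strip():
                return None
            return float(cell)

        records.append(MeasurementRecord(
            record_id=int(idx),
            participant_id=0,
            group=group,
            instruction=instruction,
            lat=_num("lat") if has_latlon else None,
            lon=_num("lon") if has_latlon else None,
            x=_num("x") if has_xy else None,
            y=_num("y") if has_xy else None,
            m1_category=m1,
            m2_height_cm=m2,
        ))
    if bad_m1:
        raise ValidationError(f"M1 category outside 1-10 on line(s) {bad_m1}")
    return records


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write records back out in the survey-CSV dialect (semicolons)."""
    df = records_to_frame(records)
    df.to_csv(path, sep=";", index=False)


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "Latitude": [r.lat for r in records],
        "Longitude": [r.lon for r in records],
        "X": [r.x for r in records],
        "Y": [r.y for r in records],
        "Participant": [r.participant_id for r in records],
        "Instruction Type": [r.instruction for r in records],
        "Crop Height - M1": [r.m1_category for r in records],
        "Crop Height - M2 (cm)": [r.m2_height_cm for r in records],
    })
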