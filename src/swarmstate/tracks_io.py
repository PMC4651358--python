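"""Track and raster I/O with validation.

Tracks are hourly GPS fixes in planar metre coordinates (British National
Grid-style eastings/northings; the ~1 km² plot justifies planar distance, so
no geodesy anywhere). Environment rasters hold a time-invariant vegetation
mosaic and an hourly thermal-stress stack (power consumption of a heated
mechanical animal model, a W/kg^0.75-scale proxy for heat loss).

The track CSV dialect is configurable because deposited telemetry files vary
in header names and timestamp formats; the default matches the layout
``ear_tag, species, timestamp, E, N[, Veg_Summ]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Species", "Track", "EnvironmentRaster", "StudyConfig", "TrackDialect",
    "TrackFormatError", "TrackValidationError", "RasterLookupError",
    "read_tracks", "write_tracks", "point_lookup",
    "read_raster_ascii", "write_raster_ascii",
    "VEGETATION_CLASSES", "season_of_month", "SEASON_RULE_DEFAULT",
    "SEASON_RULE_TABLE1",
]

#: Vegetation classes of the moorland mosaic.
VEGETATION_CLASSES = ("bracken", "dry heath", "wet heath", "grass", "rock", "rushes")

#: Month -> season, following the Methods-text rule (summer April-November).
SEASON_RULE_DEFAULT: Mapping[int, str] = {
    m: ("summer" if 4 <= m <= 11 else "winter") for m in range(1, 13)
}

#: Named preset: summer May-November, winter December-April.
SEASON_RULE_TABLE1: Mapping[int, str] = {
    m: ("summer" if 5 <= m <= 11 else "winter") for m in range(1, 13)
}


def season_of_month(month: int, rule: Mapping[int, str] | None = None) -> str:
    """Map a calendar month (1-12) to ``"summer"``/``"winter"``."""
    rule = SEASON_RULE_DEFAULT if rule is None else rule
    return rule[int(month)]


class Species(str, enum.Enum):
    SHEEP = "sheep"
    DEER = "deer"


class TrackFormatError(ValueError):
    """Raised when the input file lacks a mandatory column."""


class TrackValidationError(ValueError):
    """Raised on duplicate/non-monotone timestamps or unknown species."""


class RasterLookupError(ValueError):
    """Raised when a point falls outside the raster extent."""


@dataclass(frozen=True)
class TrackDialect:
    """Column-name and timestamp mapping for track CSV files."""

    animal_id: str = "ear_tag"
    species: str = "species"
    timestamp: str = "timestamp"
    easting: str = "E"
    northing: str = "N"
    habitat: str = "Veg_Summ"          # optional; carried as annotation
    timestamp_format: str | None = None  # None -> pandas inference (ISO-8601)


@dataclass
class Track:
    """One animal's hourly positions.

    ``positions`` rows aligned to ``times``; missing fixes are explicit NaN
    rows (never silently dropped, never interpolated). ``habitat`` is an
    optional per-fix annotation string array.
    """

    animal_id: str
    species: Species
    times: pd.DatetimeIndex
    positions: np.ndarray  # (T, 2) float, columns (easting_m, northing_m)
    habitat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrackValidationError(
                f"{self.animal_id}: positions must be (T, 2), got {self.positions.shape}"
            )
        if len(self.times) != len(self.positions):
            raise TrackValidationError(f"{self.animal_id}: times/positions length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times.view("i8"))
            if np.any(dt <= 0):
                bad = np.nonzero(dt <= 0)[0]
                raise TrackValidationError(
                    f"{self.animal_id}: non-increasing timestamps at rows {bad.tolist()}"
                )
        obs = self.positions[~np.isnan(self.positions).any(axis=1)]
        if obs.size and not np.all(np.isfinite(obs)):
            raise TrackValidationError(f"{self.animal_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of fixes that are present (not missing)."""
        return ~np.isnan(self.positions).any(axis=1)


@dataclass
class EnvironmentRaster:
    """Vegetation mosaic plus hourly thermal-stress stack on a common grid.

    Cells are half-open ``[x0, x0+cell) x [y0, y0+cell)``; a point on the
    max edge belongs to the last cell, so every in-extent point maps to
    exactly one cell. Grids are stored row 0 = southernmost (y origin) for
    direct index arithmetic.
    """

    origin: tuple[float, float]          # (easting, northing) of lower-left corner
    cell_size_m: float
    vegetation: np.ndarray               # (ny, nx) int codes into vegetation_classes
    vegetation_classes: Sequence[str] = VEGETATION_CLASSES
    thermal_stress: np.ndarray | None = None   # (T, ny, nx)
    thermal_times: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError(f"cell_size_m must be positive, got {self.cell_size_m}")
        self.vegetation = np.asarray(self.vegetation)
        if self.vegetation.ndim != 2:
            raise ValueError("vegetation grid must be 2-D")
        codes = np.unique(self.vegetation)
        if codes.min() < 0 or codes.max() >= len(self.vegetation_classes):
            raise ValueError("vegetation codes outside declared class set")
        if (self.thermal_stress is None) != (self.thermal_times is None):
            raise ValueError("thermal_stress and thermal_times must be given together")
        if self.thermal_stress is not None:
            self.thermal_stress = np.asarray(self.thermal_stress, dtype=float)
            if self.thermal_stress.shape[1:] != self.vegetation.shape:
                raise ValueError("thermal stack grid shape differs from vegetation grid")
            if len(self.thermal_times) != len(self.thermal_stress):
                raise ValueError("thermal stack/time index length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vegetation.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        ny, nx = self.vegetation.shape
        x0, y0 = self.origin
        return x0, y0, x0 + nx * self.cell_size_m, y0 + ny * self.cell_size_m

    def cell_index(self, point: tuple[float, float]) -> tuple[int, int]:
        """(row, col) of the cell containing ``point``; RasterLookupError if outside."""
        x, y = point
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise RasterLookupError(f"point {point} outside extent {self.extent}")
        col = int((x - xmin) / self.cell_size_m)
        row = int((y - ymin) / self.cell_size_m)
        ny, nx = self.vegetation.shape
        # max-edge points belong to the last cell (half-open convention)
        col = min(col, nx - 1)
        row = min(row, ny - 1)
        return row, col

    def contains(self, point: tuple[float, float]) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= point[0] <= xmax and ymin <= point[1] <= ymax


@dataclass
class StudyConfig:
    """Analysis-wide configuration.

    m/n are the conspecific/heterospecific neighbour counts of the
    interaction vector (1-6, matching the largest neighbourhood analysed);
    ``covariate_spec`` selects which location covariates enter the model.
    """

    m: int = 1
    n: int = 1
    season_rule: Mapping[int, str] = field(default_factory=lambda: dict(SEASON_RULE_DEFAULT))
    covariate_spec: tuple[str, ...] = ()
    rng_seed: int = 0
    dict_size: int = 60
    max_model_size: int = 25
    grid_max_m: float = 300.0
    grid_step_m: float = 5.0
    bandwidth_m: float = 10.0
    min_count: int = 30

    def __post_init__(self) -> None:
        if not (1 <= self.m <= 6 and 1 <= self.n <= 6):
            raise ValueError(f"m, n must lie in 1..6, got m={self.m}, n={self.n}")
        if set(self.season_rule) != set(range(1, 13)):
            raise ValueError("season_rule must cover all 12 months")
        bad = set(self.covariate_spec) - {"vegetation", "thermal_stress", "season"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Track CSV I/O


def read_tracks(
    path: str | Path,
    dialect: TrackDialect | None = None,
    gap_policy: str = "mark_missing",
) -> list[Track]:
    """Read a track CSV into one validated :class:`Track` per animal.

    Rows are grouped by animal id and time-sorted, so the reader is
    insensitive to input row order. Duplicate (animal, time) rows and
    unknown species strings raise :class:`TrackValidationError`. With the
    default ``gap_policy="mark_missing"`` every whole hour between an
    animal's first and last fix with no record becomes an explicit missing
    (NaN) fix; ``"none"`` keeps only observed rows.
    """
    dialect = dialect or TrackDialect()
    df = pd.read_csv(path)
    required = {
        "animal id": dialect.animal_id,
        "species": dialect.species,
        "timestamp": dialect.timestamp,
        "easting": dialect.easting,
        "northing": dialect.northing,
    }
    for what, col in required.items():
        if col not in df.columns:
            raise TrackFormatError(f"missing mandatory {what} column {col!r}")
    has_habitat = dialect.habitat in df.columns

    ts = pd.to_datetime(df[dialect.timestamp], format=dialect.timestamp_format)
    df = df.assign(_t=ts)

    dup = df.duplicated(subset=[dialect.animal_id, "_t"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise TrackValidationError(f"duplicate (animal, timestamp) rows: {rows}")

    known = {s.value for s in Species}
    bad_sp = set(df[dialect.species].astype(str).str.lower()) - known
    if bad_sp:
        raise TrackValidationError(f"unknown species strings: {sorted(bad_sp)}")

    tracks: list[Track] = []
    for aid, g in df.groupby(dialect.animal_id, sort=True):
        g = g.sort_values("_t")
        sp_vals = set(g[dialect.species].astype(str).str.lower())
        if len(sp_vals) > 1:
            raise TrackValidationError(f"{aid}: species not constant ({sorted(sp_vals)})")
        species = Species(sp_vals.pop())
        times = pd.DatetimeIndex(g["_t"])
        pos = g[[dialect.easting, dialect.northing]].to_numpy(dtype=float)
        hab = g[dialect.habitat].astype(str).to_numpy() if has_habitat else None

        if gap_policy == "mark_missing" and len(times) > 1:
            full = pd.date_range(times[0], times[-1], freq="1h")
            if len(full) != len(times) or not full.equals(times):
                frame = pd.DataFrame(pos, index=times, columns=["E", "N"])
                frame = frame.reindex(full)
                if hab is not None:
                    hs = pd.Series(hab, index=times).reindex(full)
                    hab = hs.to_numpy()
                times, pos = pd.DatetimeIndex(frame.index), frame.to_numpy()
        elif gap_policy not in ("mark_missing", "none"):
            raise ValueError(f"unknown gap_policy {gap_policy!r}")

        tracks.append(Track(str(aid), species, times, pos, habitat=hab))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path,
                 dialect: TrackDialect | None = None) -> None:
    """Write tracks to CSV in the configured dialect (missing fixes omitted)."""
    dialect = dialect or TrackDialect()
    frames = []
    for tr in tracks:
        keep = tr.observed
        rec = {
            dialect.animal_id: tr.animal_id,
            dialect.species: tr.species.value,
            dialect.timestamp: tr.times[keep].strftime("%Y-%m-%dT%H:%M:%S"),
            dialect.easting: tr.positions[keep, 0],
            dialect.northing: tr.positions[keep, 1],
        }
        if tr.habitat is not None:
            rec[dialect.habitat] = np.asarray(tr.habitat)[keep]
        frames.append(pd.DataFrame(rec))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster I/O and lookup


def point_lookup(
    raster: EnvironmentRaster,
    point: tuple[float, float],
    time: pd.Timestamp | None = None,
    max_time_gap: pd.Timedelta = pd.Timedelta(minutes=30),
) -> tuple[str, float | None]:
    """Vegetation class and thermal-stress value at ``point``.

    Thermal value is taken from the stack layer nearest in time (within
    ``max_time_gap``, else None); vegetation is time-invariant. Raises
    :class:`RasterLookupError` for out-of-extent points and ``ValueError``
    when a thermal value is requested but the raster has no stack.
    """
    row, col = raster.cell_index(point)
    veg = raster.vegetation_classes[int(raster.vegetation[row, col])]
    if time is None:
        return veg, None
    if raster.thermal_stress is None:
        raise ValueError("thermal stress requested but raster has no thermal stack")
    i = int(raster.thermal_times.get_indexer([pd.Timestamp(time)], method="nearest")[0])
    if abs(raster.thermal_times[i] - pd.Timestamp(time)) > max_time_gap:
        return veg, None
    return veg, float(raster.thermal_stress[i, row, col])


def write_raster_ascii(raster: EnvironmentRaster, path: str | Path) -> None:
    """Write the vegetation grid as an ESRI-ASCII-style plain-text grid.

    The header carries the class list on a trailing comment-style line so the
    grid round-trips with class names intact. The thermal stack, being
    time-indexed, is not part of this format.
    """
    ny, nx = raster.shape
    x0, y0 = raster.origin
    lines = [
        f"ncols {nx}",
        f"nrows {ny}",
        f"xllcorner {x0}",
        f"yllcorner {y0}",
        f"cellsize {raster.cell_size_m}",
        "NODATA_value -9999",
    ]
    # ESRI ASCII stores the top row first
    for r in range(ny - 1, -1, -1):
        lines.append(" ".join(str(int(v)) for v in raster.vegetation[r]))
    lines.append("# classes: " + ";".join(raster.vegetation_classes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_raster_ascii(path: str | Path) -> EnvironmentRaster:
    """Read a vegetation grid written by :func:`write_raster_ascii`."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    nx, ny = int(hdr["ncols"]), int(hdr["nrows"])
    rows = []
    for j in range(ny):
        rows.append([int(v) for v in lines[i + j].split()])
    grid = np.asarray(rows[::-1])  # back to row 0 = south
    classes: Sequence[str] = VEGETATION_CLASSES
    for line in lines[i + ny:]:
        if line.startswith("# classes:"):
            classes = tuple(line.split(":", 1)[1].strip().split(";"))
    return EnvironmentRaster(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_size_m=hdr["cellsize"],
        vegetation=grid,
        vegetation_classes=classes,
    )
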