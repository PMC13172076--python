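"""Linking participant locations to environmental layers.

Participants come in as a CSV of (subject id, WGS84 longitude, latitude),
optionally ordered per route. For every complete single-band raster in a
store the linker transforms the coordinates into the layer's native CRS,
samples the half-open cell containing each point and writes one CSV per
layer. Gridded time-series cubes produce a compact JSON instead: because
cube pixels are coarse relative to participant density, subjects falling
in the same pixel are grouped and the pixel's full time series is stored
once per group.

Privacy helpers (uniform-disk jittering and grid snapping) let data
holders coarsen coordinates before linkage where governance requires it;
jitter offsets are derived per subject from a counter-based hash so they
are stable under row reordering.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path, PurePosixPath
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError
from .grids import GridCube, RasterGrid
from .metrics import METERS_PER_DEGREE
from .projection import ProjectionSpec, transform_points
from .store import StoreManifest, read_cube, read_raster, scan_store

_ID_ALIASES = {"subject_id", "subject id", "subjectid", "id"}
_LON_ALIASES = {"longitude", "lon", "lng"}
_LAT_ALIASES = {"latitude", "lat"}


@dataclass
class ParticipantTable:
    """Validated participant locations (WGS84), optionally route-ordered."""

    subject_ids: list[str]
    lons: np.ndarray
    lats: np.ndarray
    route_ids: list[str] | None = None
    sequences: list[int] | None = None

    def __len__(self) -> int:
        return len(self.subject_ids)

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.lons.tolist(), self.lats.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_ids, "longitude": self.lons, "latitude": self.lats}
        )
        if self.route_ids is not None:
            df["route_id"] = self.route_ids
            df["sequence"] = self.sequences
        return df


def make_participants(
    subject_ids: Sequence[str],
    lons: Sequence[float],
    lats: Sequence[float],
    route_ids: Sequence[str] | None = None,
    sequences: Sequence[int] | None = None,
) -> ParticipantTable:
    lons = np.asarray(lons, dtype=np.float64)
    lats = np.asarray(lats, dtype=np.float64)
    if not (len(subject_ids) == len(lons) == len(lats)):
        raise ValidationError("subject_ids, lons, lats must have equal length")
    for i, sid in enumerate(subject_ids):
        if not str(sid):
            raise ValidationError(f"empty subject id at row {i + 1}")
    bad_lon = np.where((lons < -180) | (lons > 180))[0]
    if bad_lon.size:
        raise ValidationError(
            f"longitude {lons[bad_lon[0]]} out of [-180, 180] at row {bad_lon[0] + 1}"
        )
    bad_lat = np.where((lats < -90) | (lats > 90))[0]
    if bad_lat.size:
        raise ValidationError(
            f"latitude {lats[bad_lat[0]]} out of [-90, 90] at row {bad_lat[0] + 1}"
        )
    if route_ids is not None:
        pairs = list(zip(route_ids, sequences))
        if len(pairs) != len(set(pairs)):
            raise ValidationError("(route_id, sequence) pairs must be unique")
    else:
        ids = [str(s) for s in subject_ids]
        if len(ids) != len(set(ids)):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise ValidationError(f"duplicate subject_id {dup!r}")
    return ParticipantTable(
        [str(s) for s in subject_ids], lons, lats,
        list(route_ids) if route_ids is not None else None,
        [int(s) for s in sequences] if sequences is not None else None,
    )


def read_locations(path: str | os.PathLike) -> ParticipantTable:
    """Read a locations CSV; headers matched case-insensitively."""
    try:
        df = pd.read_csv(path, dtype={})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read locations file {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}

    def pick(aliases: set[str], label: str) -> str:
        for a in aliases:
            if a in cols:
                return cols[a]
        raise FormatError(f"locations file {path} is missing a {label!r} column")

    id_col = pick(_ID_ALIASES, "subject_id")
    lon_col = pick(_LON_ALIASES, "longitude")
    lat_col = pick(_LAT_ALIASES, "latitude")
    route_col = cols.get("route_id")
    seq_col = cols.get("sequence")
    return make_participants(
        df[id_col].astype(str).tolist(),
        df[lon_col].to_numpy(dtype=np.float64),
        df[lat_col].to_numpy(dtype=np.float64),
        df[route_col].astype(str).tolist() if route_col else None,
        df[seq_col].tolist() if route_col and seq_col else None,
    )


# ---------------------------------------------------------------------------
# sampling


def point_to_pixel(grid: RasterGrid, x: float, y: float) -> tuple[int, int] | None:
    """(row, col) of the half-open cell containing (x, y), or None outside."""
    t = grid.transform
    col = math.floor((x - t.x_origin) / t.x_size)
    row = math.floor((t.y_origin - y) / t.y_size)
    rows, cols = grid.shape
    if 0 <= row < rows and 0 <= col < cols:
        return row, col
    return None


def sample_raster(
    grid: RasterGrid, points: Iterable[tuple[float, float]]
) -> list[float | None]:
    """Value of the cell containing each point; None outside or on nodata."""
    valid = grid.valid_mask()
    out: list[float | None] = []
    for x, y in points:
        rc = point_to_pixel(grid, x, y)
        if rc is None or not valid[rc]:
            out.append(None)
        else:
            out.append(float(grid.values[rc]))
    return out


def _native_points(participants: ParticipantTable, crs_id: str) -> list[tuple[float, float]]:
    return transform_points(participants.points(), ProjectionSpec.from_crs_id(crs_id))


def layer_column_name(store_root: str | os.PathLike, layer_rel: str) -> str:
    """``<source>__<variable>__<year-or-tag>`` from a store-relative path."""
    p = PurePosixPath(layer_rel)
    source, variable = p.parts[0], p.parts[1]
    stem = p.stem
    prefix = f"{source}_{variable}_"
    tag = stem[len(prefix):] if stem.startswith(prefix) else stem
    return f"{source}__{variable}__{tag}"


def link_rasters(
    store_root: str | os.PathLike,
    participants: ParticipantTable,
    out_dir: str | os.PathLike,
    manifest: StoreManifest | None = None,
) -> tuple[list[str], list[str]]:
    """Sample every complete GeoTIFF layer; one CSV per layer.

    Returns (written CSV paths, warnings). Incomplete layers are skipped
    with a warning; rows are emitted in input order with empty fields for
    subjects outside a layer's extent.
    """
    store_root = Path(store_root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or scan_store(store_root)
    written: list[str] = []
    warn: list[str] = []
    for entry in manifest.entries:
        if not entry.path.endswith(".tif"):
            continue
        if entry.status != "complete":
            warn.append(f"layer {entry.path} is incomplete; skipped")
            continue
        grid = read_raster(store_root / entry.path)
        pts = _native_points(participants, grid.crs_id)
        values = sample_raster(grid, pts)
        column = layer_column_name(store_root, entry.path)
        df = pd.DataFrame({"subject_id": participants.subject_ids, column: values})
        out_path = out_dir / (PurePosixPath(entry.path).stem + ".csv")
        df.to_csv(out_path, index=False)
        written.append(str(out_path))
    return written, warn


# ---------------------------------------------------------------------------
# cube linkage with same-pixel grouping


@dataclass
class PixelGroup:
    pixel: tuple[int, int]
    series: list[float]
    subjects: list[str]


@dataclass
class LinkedCubeResult:
    variable: str
    crs_id: str
    times: list[str]
    groups: list[PixelGroup]
    unmatched: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable": self.variable,
                "crs": self.crs_id,
                "time": self.times,
                "groups": [
                    {
                        "pixel": list(g.pixel),
                        "series": [None if v is None or (isinstance(v, float) and math.isnan(v)) else v
                                   for v in g.series],
                        "subjects": g.subjects,
                    }
                    for g in self.groups
                ],
                "unmatched": self.unmatched,
            }
        )


def link_cube(cube: GridCube, participants: ParticipantTable) -> LinkedCubeResult:
    """Group subjects by cube pixel; store each occupied pixel's series once."""
    probe = RasterGrid(cube.values[0], cube.transform, cube.crs_id, cube.nodata)
    pts = _native_points(participants, cube.crs_id)
    by_pixel: dict[tuple[int, int], list[str]] = {}
    unmatched: list[str] = []
    for sid, (x, y) in zip(participants.subject_ids, pts):
        rc = point_to_pixel(probe, x, y)
        if rc is None:
            unmatched.append(sid)
        else:
            by_pixel.setdefault(rc, []).append(sid)
    nod = cube.nodata
    groups = []
    for rc in sorted(by_pixel):
        series = cube.values[:, rc[0], rc[1]].astype(float)
        cleaned = [None if (nod is not None and v == nod) or math.isnan(v) else float(v)
                   for v in series]
        groups.append(PixelGroup(rc, cleaned, by_pixel[rc]))
    times = np.datetime_as_string(cube.times, unit="s").tolist()
    return LinkedCubeResult(cube.variable, cube.crs_id, times, groups, unmatched)


def link_cubes(
    store_root: str | os.PathLike,
    participants: ParticipantTable,
    out_dir: str | os.PathLike,
    manifest: StoreManifest | None = None,
) -> tuple[list[str], list[str]]:
    """Link every complete netCDF layer; one JSON per layer."""
    store_root = Path(store_root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or scan_store(store_root)
    written: list[str] = []
    warn: list[str] = []
    for entry in manifest.entries:
        if not entry.path.endswith(".nc"):
            continue
        if entry.status != "complete":
            warn.append(f"layer {entry.path} is incomplete; skipped")
            continue
        result = link_cube(read_cube(store_root / entry.path), participants)
        out_path = out_dir / (PurePosixPath(entry.path).stem + ".json")
        out_path.write_text(result.to_json())
        written.append(str(out_path))
    return written, warn


# ---------------------------------------------------------------------------
# routes


@dataclass
class RouteSummary:
    values: list[float | None]
    mean: float | None
    min: float | None
    max: float | None


def link_route(
    route_points: Sequence[tuple[float, float]], grid: RasterGrid
) -> RouteSummary:
    """Sample an ordered WGS84 route and summarise its valid samples."""
    if not route_points:
        raise ValidationError("a route needs at least one point")
    pts = transform_points(route_points, ProjectionSpec.from_crs_id(grid.crs_id))
    values = sample_raster(grid, pts)
    valid = [v for v in values if v is not None]
    if not valid:
        return RouteSummary(values, None, None, None)
    return RouteSummary(values, float(np.mean(valid)), min(valid), max(valid))


# ---------------------------------------------------------------------------
# privacy utilities


def _unit_uniforms(seed: int, subject_id: str) -> tuple[float, float]:
    # counter-based: one hash per subject, stable under row reordering
    digest = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    u1 = int.from_bytes(digest[:8], "big") / 2**64
    u2 = int.from_bytes(digest[8:16], "big") / 2**64
    return u1, u2


def jitter_coordinates(
    participants: ParticipantTable, max_offset_m: float, seed: int
) -> ParticipantTable:
    """Displace each point uniformly within a disk of ``max_offset_m``."""
    if max_offset_m < 0:
        raise ParameterError(f"max offset must be >= 0, got {max_offset_m}")
    if max_offset_m == 0:
        return replace(participants)
    lons = participants.lons.copy()
    lats = participants.lats.copy()
    for i, sid in enumerate(participants.subject_ids):
        u1, u2 = _unit_uniforms(seed, sid)
        r = max_offset_m * math.sqrt(u1)
        theta = 2 * math.pi * u2
        dx, dy = r * math.cos(theta), r * math.sin(theta)
        lats[i] += dy / METERS_PER_DEGREE
        lons[i] += dx / (METERS_PER_DEGREE * math.cos(math.radians(participants.lats[i])))
    return ParticipantTable(
        list(participants.subject_ids), lons, lats,
        participants.route_ids, participants.sequences,
    )


def snap_to_grid(participants: ParticipantTable, cell_deg: float) -> ParticipantTable:
    """Replace each coordinate by the center of its cell (anchored at 0 deg)."""
    if cell_deg <= 0:
        raise ParameterError(f"cell size must be > 0, got {cell_deg}")
    lons = (np.floor(participants.lons / cell_deg) + 0.5) * cell_deg
    lats = (np.floor(participants.lats / cell_deg) + 0.5) * cell_deg
    return ParticipantTable(
        list(participants.subject_ids), lons, lats,
        participants.route_ids, participants.sequences,
    )
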