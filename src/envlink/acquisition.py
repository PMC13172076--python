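"""Provider adapters and spatial assembly.

A *provider* is anything that can deliver the layers for one (source,
variable, year) request — possibly as several tiles. Real download
clients (climate-store APIs, web map services, direct links) are modelled
by stub adapters carrying the credential-file contract; the
:class:`FixtureProvider` serves pre-generated files from a local
directory and is what every test and offline run uses.

Assembly consists of clipping fetched layers to the configured bounding
box (a pixel belongs to the subset iff its *center* falls inside the box)
and stitching grid-aligned tiles into a seamless mosaic.
:func:`materialize` runs fetch -> subset -> stitch -> write for one job
and marks it complete with a checksum sentinel only after the data file
is fully written, which makes interrupted builds safely resumable.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Union

import numpy as np
import pandas as pd

from .config import BoundingBox, Job, SourceSpec, WorkflowConfig
from .errors import EmptyExtentError, FetchError, StitchError
from .grids import GridCube, GridTransform, RasterGrid
from .store import (
    dataset_path,
    is_complete,
    read_cube,
    read_raster,
    read_table,
    write_cube,
    write_raster,
    write_sentinel,
    write_table,
)

Layer = Union[RasterGrid, GridCube, pd.DataFrame]

SECRET_FILES = {
    "cds_climate": "cdsapirc_climate.sct",
    "cds_atmo": "cdsapirc_atmo.sct",
    "nasa": "nasa.sct",
}


@dataclass(frozen=True)
class ProviderRequest:
    source_id: str
    variable: str
    year: str  # 4-digit year or "static"
    bbox: BoundingBox


@dataclass(frozen=True)
class CredentialRef:
    provider_key: str
    secret_file: str

    def resolve(self, secrets_folder: str | os.PathLike) -> Path:
        path = Path(secrets_folder) / self.secret_file
        if not path.is_file():
            raise FetchError(
                f"credential file {self.secret_file!r} not found in {secrets_folder}"
            )
        return path


class Provider(Protocol):
    def fetch(self, request: ProviderRequest) -> list[Layer]: ...


class StubNetworkProvider:
    """Placeholder for real network adapters; always raises.

    Keeps the external interface (URL + named credential files) without
    shipping network code.
    """

    def __init__(self, source_id: str, url: str, credential: CredentialRef | None = None):
        self.source_id = source_id
        self.url = url
        self.credential = credential

    def fetch(self, request: ProviderRequest) -> list[Layer]:
        raise FetchError(
            f"network provider for {self.source_id!r} is not configured in this "
            f"deployment (url: {self.url})"
        )


class FixtureProvider:
    """Serves layers from a local directory laid out like the store.

    Files live at ``root/<source>/<variable>/<source>_<variable>_<year>.<ext>``;
    a subdirectory ``tiles/`` beside a raster holds a tiled variant
    (``..._tile0.tif`` etc.) which, when present, is returned instead of
    the single file to exercise stitching.
    """

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)

    def fetch(self, request: ProviderRequest) -> list[Layer]:
        for fmt in ("geotiff", "netcdf", "csv"):
            path = Path(dataset_path(self.root, request.source_id, request.variable,
                                     request.year, fmt))
            tiles_dir = path.parent / "tiles"
            if fmt == "geotiff" and tiles_dir.is_dir():
                tiles = sorted(tiles_dir.glob(f"{path.stem}_tile*.tif"))
                if tiles:
                    return [read_raster(t) for t in tiles]
            if path.is_file():
                if fmt == "geotiff":
                    return [read_raster(path)]
                if fmt == "netcdf":
                    return [read_cube(path)]
                return [read_table(path)]
        raise FetchError(
            f"fixture provider has no data for ({request.source_id}, "
            f"{request.variable}, {request.year}) under {self.root}"
        )


class FlakyProvider:
    """Wraps a provider and fails according to a script; for resume tests."""

    def __init__(self, inner: Provider, fail_keys: dict[tuple[str, str, str], int]):
        self.inner = inner
        self.remaining = dict(fail_keys)

    def fetch(self, request: ProviderRequest) -> list[Layer]:
        key = (request.source_id, request.variable, request.year)
        if self.remaining.get(key, 0) > 0:
            self.remaining[key] -= 1
            raise FetchError(f"scripted failure for {key}")
        return self.inner.fetch(request)


def make_provider(source: SourceSpec, secrets_folder: str | os.PathLike = "") -> Provider:
    if source.access_kind == "fixture":
        return FixtureProvider(source.url)
    cred = None
    if source.access_kind == "api":
        cred = CredentialRef(source.source_id, f"{source.source_id}.sct")
    return StubNetworkProvider(source.source_id, source.url, cred)


# ---------------------------------------------------------------------------
# spatial assembly


def _center_range(origin: float, size: float, n: int, lo: float, hi: float,
                  descending: bool = False) -> tuple[int, int]:
    """Index range [i0, i1) whose pixel centers fall inside [lo, hi]."""
    if descending:
        # y axis: center(i) = origin - (i + 0.5) * size, decreasing in i
        i0 = max(0, math.ceil((origin - hi) / size - 0.5))
        i1 = min(n, math.floor((origin - lo) / size - 0.5) + 1)
    else:
        i0 = max(0, math.ceil((lo - origin) / size - 0.5))
        i1 = min(n, math.floor((hi - origin) / size - 0.5) + 1)
    return i0, i1


def subset_to_bbox(grid: RasterGrid, bbox: BoundingBox) -> RasterGrid:
    """Clip to exactly the pixels whose centers fall inside the box."""
    rows, cols = grid.shape
    t = grid.transform
    c0, c1 = _center_range(t.x_origin, t.x_size, cols, bbox.west, bbox.east)
    r0, r1 = _center_range(t.y_origin, t.y_size, rows, bbox.south, bbox.north,
                           descending=True)
    if r0 >= r1 or c0 >= c1:
        raise EmptyExtentError(
            f"bbox {bbox.as_list()} contains no pixel centers of the grid"
        )
    new_t = GridTransform(
        t.x_origin + c0 * t.x_size, t.y_origin - r0 * t.y_size, t.x_size, t.y_size
    )
    return RasterGrid(grid.values[r0:r1, c0:c1].copy(), new_t, grid.crs_id, grid.nodata)


def subset_cube_to_bbox(cube: GridCube, bbox: BoundingBox) -> GridCube:
    probe = RasterGrid(cube.values[0], cube.transform, cube.crs_id, cube.nodata)
    sub = subset_to_bbox(probe, bbox)
    rows, cols = cube.values.shape[1:]
    t = cube.transform
    c0 = round((sub.transform.x_origin - t.x_origin) / t.x_size)
    r0 = round((t.y_origin - sub.transform.y_origin) / t.y_size)
    nr, nc = sub.shape
    return GridCube(
        cube.values[:, r0:r0 + nr, c0:c0 + nc].copy(), cube.times, sub.transform,
        cube.crs_id, cube.nodata, cube.variable,
    )


def stitch_tiles(tiles: list[RasterGrid], first_wins: bool = False) -> RasterGrid:
    """Mosaic grid-aligned tiles; uncovered cells become nodata.

    In strict mode (default) overlapping cells with conflicting valid
    values raise; ``first_wins`` keeps the earlier tile's value instead.
    """
    if not tiles:
        raise StitchError("no tiles to stitch")
    if len(tiles) == 1:
        return tiles[0]
    ref = tiles[0]
    dx, dy = ref.transform.x_size, ref.transform.y_size
    for tile in tiles[1:]:
        if tile.crs_id != ref.crs_id:
            raise StitchError(f"CRS mismatch: {tile.crs_id!r} vs {ref.crs_id!r}")
        if not (math.isclose(tile.transform.x_size, dx) and math.isclose(tile.transform.y_size, dy)):
            raise StitchError("pixel size mismatch between tiles")
        for off, size in (
            ((tile.transform.x_origin - ref.transform.x_origin), dx),
            ((tile.transform.y_origin - ref.transform.y_origin), dy),
        ):
            if abs(off / size - round(off / size)) > 1e-6:
                raise StitchError("tiles are not aligned on a common grid")
    x_min = min(t.transform.x_origin for t in tiles)
    y_max = max(t.transform.y_origin for t in tiles)
    x_max = max(t.transform.x_origin + t.shape[1] * dx for t in tiles)
    y_min = min(t.transform.y_origin - t.shape[0] * dy for t in tiles)
    rows = round((y_max - y_min) / dy)
    cols = round((x_max - x_min) / dx)
    nodata = ref.nodata if ref.nodata is not None else float(np.nan)
    out = np.full((rows, cols), nodata, dtype=np.result_type(*(t.values.dtype for t in tiles), np.float64)
                  if ref.nodata is None else ref.values.dtype)
    filled = np.zeros((rows, cols), dtype=bool)
    for tile in tiles:
        r0 = round((y_max - tile.transform.y_origin) / dy)
        c0 = round((tile.transform.x_origin - x_min) / dx)
        tr, tc = tile.shape
        window = (slice(r0, r0 + tr), slice(c0, c0 + tc))
        tvalid = tile.valid_mask()
        overlap = filled[window] & tvalid
        if overlap.any() and not first_wins:
            conflict = overlap & (out[window] != tile.values) & ~(
                np.isnan(out[window].astype(float)) & np.isnan(tile.values.astype(float))
                if np.issubdtype(tile.values.dtype, np.floating) else np.zeros_like(overlap)
            )
            if conflict.any():
                raise StitchError("overlapping tiles carry conflicting values")
        write_mask = tvalid & ~(filled[window] if first_wins else np.zeros_like(tvalid))
        out[window][write_mask] = tile.values[write_mask]
        filled[window] |= tvalid
    return RasterGrid(
        out, GridTransform(x_min, y_max, dx, dy), ref.crs_id,
        ref.nodata if ref.nodata is not None else None,
    )


# ---------------------------------------------------------------------------
# job materialization


def materialize(
    job: Job,
    provider: Provider,
    store_root: str | os.PathLike,
    bbox: BoundingBox,
    first_wins: bool = False,
) -> str:
    """Fetch, assemble and persist one job; idempotent once complete.

    The sentinel is written only after the data file; any failure leaves
    either no file or a file without sentinel, so a rescan classifies the
    job incomplete and a rerun picks it up again.
    """
    target = Path(store_root) / job.target
    if is_complete(target):
        return str(target)
    layers = provider.fetch(ProviderRequest(job.source_id, job.variable, job.year, bbox))
    if not layers:
        raise FetchError(f"provider returned no layers for {job.key}")
    first = layers[0]
    if isinstance(first, RasterGrid):
        clipped = []
        for layer in layers:
            try:
                clipped.append(subset_to_bbox(layer, bbox))
            except EmptyExtentError:
                continue  # tile entirely outside the area
        if not clipped:
            raise EmptyExtentError(f"no fetched tile intersects the area for {job.key}")
        grid = stitch_tiles(clipped, first_wins=first_wins) if len(clipped) > 1 else clipped[0]
        write_raster(grid, target)
    elif isinstance(first, GridCube):
        write_cube(subset_cube_to_bbox(first, bbox), target)
    else:
        write_table(first, target)
    write_sentinel(target)
    return str(target)
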