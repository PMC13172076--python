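"""The on-disk harmonized database.

Layout is ``root/<source>/<variable>/<source>_<variable>_<year>.<ext>``
with one file per (source, variable, year) — netCDF for gridded
time series, GeoTIFF for single-band rasters, CSV for regional indicator
tables. Completeness is tracked by a sentinel file ``<file>.ok`` holding
the SHA-256 of the data file, written only after the data file is fully
on disk; :func:`scan_store` rebuilds the manifest from sentinels so an
interrupted build can resume exactly where it stopped.

GeoTIFF georeferencing is written as standard tags (ModelPixelScale,
ModelTiepoint, a minimal GeoKeyDirectory, GDAL-style nodata) plus a JSON
ImageDescription that round-trips the CRS identifier and nodata value
exactly. netCDF files are CF-style NETCDF3 with (time, y, x) dimensions,
one named data variable per file, and the geotransform recorded in global
attributes.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
from dataclasses import dataclass
from pathlib import Path, PurePosixPath
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .errors import NamingError, StoreIOError, ValidationError
from .grids import GridCube, GridTransform, RasterGrid

_IDENT_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_EXT = {"geotiff": "tif", "netcdf": "nc", "csv": "csv"}

DATA_SUFFIXES = (".tif", ".nc", ".csv")
SENTINEL_SUFFIX = ".ok"


def dataset_path(
    root: str | os.PathLike,
    source_id: str,
    variable: str,
    year: str,
    fmt: Literal["geotiff", "netcdf", "csv"],
) -> str:
    """Deterministic store path for one (source, variable, year) layer."""
    for ident in (source_id, variable, str(year)):
        if not _IDENT_RE.match(str(ident)):
            raise NamingError(
                f"identifier {ident!r} contains characters outside [A-Za-z0-9_-]"
            )
    if fmt not in _EXT:
        raise NamingError(f"unknown storage format {fmt!r}")
    rel = PurePosixPath(source_id) / variable / f"{source_id}_{variable}_{year}.{_EXT[fmt]}"
    return str(PurePosixPath(str(root)) / rel) if str(root) else str(rel)


# ---------------------------------------------------------------------------
# GeoTIFF

_EPSG_RE = re.compile(r"^EPSG:(\d+)$", re.IGNORECASE)


def _geokeys(crs_id: str) -> tuple[int, ...]:
    m = _EPSG_RE.match(crs_id or "")
    code = int(m.group(1)) if m else 0
    if code == 4326:
        #           header          model=geographic  raster=PixelIsArea  GCS code
        return (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)
    if 0 < code < 65535:
        return (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, code)
    return (1, 1, 0, 2, 1024, 0, 1, 32767, 1025, 0, 1, 1)  # user-defined CRS


def write_raster(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write a single-band GeoTIFF; parent directories are created."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = grid.transform
    desc = json.dumps(
        {"crs_id": grid.crs_id, "nodata": grid.nodata},
    )
    extratags = [
        (33550, "d", 3, (t.x_size, t.y_size, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
    ]
    keys = _geokeys(grid.crs_id)
    extratags.append((34735, "H", len(keys), keys))
    if grid.nodata is not None:
        extratags.append((42113, "s", 0, repr(grid.nodata)))
    tifffile.imwrite(path, grid.values, description=desc, extratags=extratags)


def read_raster(path: str | os.PathLike) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            sx, sy = 1.0, 1.0
            x0, y0 = 0.0, 0.0
            if 33550 in tags:
                sx, sy = tags[33550].value[0], tags[33550].value[1]
            if 33922 in tags:
                tp = tags[33922].value
                x0, y0 = tp[3], tp[4]
            crs_id, nodata = "EPSG:4326", None
            if 270 in tags:
                try:
                    meta = json.loads(tags[270].value)
                    crs_id = meta.get("crs_id", crs_id)
                    nodata = meta.get("nodata")
                except (json.JSONDecodeError, TypeError):
                    pass
            if nodata is None and 42113 in tags:
                try:
                    nodata = float(tags[42113].value)
                except ValueError:
                    pass
    except (OSError, tifffile.TiffFileError, IndexError) as exc:
        raise StoreIOError(f"cannot read raster {path}: {exc}") from exc
    return RasterGrid(values, GridTransform(x0, y0, sx, sy), crs_id, nodata)


# ---------------------------------------------------------------------------
# netCDF cubes


def write_cube(cube: GridCube, path: str | os.PathLike) -> None:
    """Write a (time, y, x) cube as CF-style NETCDF3."""
    if len(cube.times) > 1 and not (np.diff(cube.times.astype("int64")) > 0).all():
        raise ValidationError("cube times must be strictly increasing")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = cube.transform
    nrows, ncols = cube.values.shape[1:]
    da = xr.DataArray(
        cube.values,
        dims=("time", "y", "x"),
        coords={
            "time": cube.times,
            "y": t.y_centers(nrows),
            "x": t.x_centers(ncols),
        },
        name=cube.variable,
    )
    ds = da.to_dataset()
    ds.attrs.update(
        crs_id=cube.crs_id,
        x_origin=t.x_origin,
        y_origin=t.y_origin,
        x_size=t.x_size,
        y_size=t.y_size,
    )
    if cube.nodata is not None:
        ds.attrs["nodata"] = float(cube.nodata)
    ds.to_netcdf(
        path,
        engine="scipy",
        format="NETCDF3_CLASSIC",
        encoding={"time": {"units": "seconds since 1970-01-01", "dtype": "float64"}},
    )


def read_cube(path: str | os.PathLike) -> GridCube:
    try:
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
    except (OSError, ValueError, TypeError) as exc:
        raise StoreIOError(f"cannot read cube {path}: {exc}") from exc
    names = [n for n in ds.data_vars if set(ds[n].dims) == {"time", "y", "x"}]
    if not names:
        raise StoreIOError(f"cannot read cube {path}: no (time, y, x) variable found")
    name = names[0]
    a = ds.attrs
    transform = GridTransform(
        float(a["x_origin"]), float(a["y_origin"]), float(a["x_size"]), float(a["y_size"])
    )
    nodata = float(a["nodata"]) if "nodata" in a else None
    return GridCube(
        values=ds[name].transpose("time", "y", "x").values,
        times=ds["time"].values,
        transform=transform,
        crs_id=str(a.get("crs_id", "EPSG:4326")),
        nodata=nodata,
        variable=name,
    )


# ---------------------------------------------------------------------------
# CSV indicator tables (stored verbatim; no geometry attached)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StoreIOError(f"cannot read table {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# completeness manifest


def file_checksum(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sentinel(path: str | os.PathLike) -> None:
    """Mark a data file complete by recording its SHA-256 beside it."""
    Path(str(path) + SENTINEL_SUFFIX).write_text(file_checksum(path) + "\n")


def is_complete(path: str | os.PathLike) -> bool:
    sentinel = Path(str(path) + SENTINEL_SUFFIX)
    if not Path(path).exists() or not sentinel.exists():
        return False
    return sentinel.read_text().strip() == file_checksum(path)


@dataclass
class ManifestEntry:
    path: str  # relative to the store root, posix separators
    checksum: str
    status: Literal["complete", "incomplete"]


@dataclass
class StoreManifest:
    entries: list[ManifestEntry]

    def complete_paths(self) -> set[str]:
        return {e.path for e in self.entries if e.status == "complete"}

    def checksums(self) -> dict[str, str]:
        return {e.path: e.checksum for e in self.entries}


def scan_store(root: str | os.PathLike) -> StoreManifest:
    """Walk the store and classify every data file by its sentinel."""
    root = Path(root)
    entries = []
    for path in sorted(root.rglob("*")):
        if path.suffix not in DATA_SUFFIXES or not path.is_file():
            continue
        checksum = file_checksum(path)
        status = "complete" if is_complete(path) else "incomplete"
        rel = str(PurePosixPath(path.relative_to(root).as_posix()))
        entries.append(ManifestEntry(rel, checksum, status))
    return StoreManifest(entries)
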