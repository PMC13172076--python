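"""Seeded synthetic inputs standing in for remote providers.

Every generator is bit-deterministic under a fixed seed, so pipelines
built on fixtures can be compared checksum-for-checksum across runs.
Plane fields make the terrain derivatives and focal means analytically
checkable; seeded noise exercises the statistics; constant fields make
end-to-end invariants trivial to assert. Fixtures default to small
(sub-degree) geographic windows so degree/meter conversions are
exercised without large arrays. These fields are structural test
surfaces, not physically realistic climatologies.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .config import BoundingBox, SourceSpec
from .errors import ParameterError
from .grids import GridCube, GridTransform, RasterGrid
from .linkage import ParticipantTable, make_participants
from .store import dataset_path, write_cube, write_raster, write_sentinel, write_table

FieldKind = Literal["constant", "plane", "gaussian_bump", "seeded_noise", "checkerboard"]

DEFAULT_EXTENT = BoundingBox(north=52.6, west=13.0, south=52.0, east=13.8)


@dataclass(frozen=True)
class FixtureField:
    """Recipe for one synthetic raster field."""

    kind: FieldKind = "plane"
    a: float = 1.0          # plane: value = a*x + b*y + c at pixel centers
    b: float = 0.0
    c: float = 0.0
    amplitude: float = 1.0  # gaussian bump height
    width: float = 0.1      # gaussian bump sigma, CRS units
    seed: int = 0
    extent: BoundingBox = DEFAULT_EXTENT
    resolution: float = 0.01  # CRS units per pixel
    crs_id: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ParameterError(f"resolution must be > 0, got {self.resolution}")
        for name in ("a", "b", "c", "amplitude", "width"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"parameter {name} must be finite")


def _field_values(f: FixtureField, step: int = 0) -> tuple[np.ndarray, GridTransform]:
    cols = int(round((f.extent.east - f.extent.west) / f.resolution))
    rows = int(round((f.extent.north - f.extent.south) / f.resolution))
    if rows < 1 or cols < 1:
        raise ParameterError("extent is degenerate at this resolution")
    t = GridTransform(f.extent.west, f.extent.north, f.resolution, f.resolution)
    x = t.x_centers(cols)[None, :]
    y = t.y_centers(rows)[:, None]
    if f.kind == "constant":
        vals = np.full((rows, cols), float(f.c))
    elif f.kind == "plane":
        vals = f.a * x + f.b * y + f.c + np.zeros((rows, cols))
    elif f.kind == "gaussian_bump":
        cx = (f.extent.west + f.extent.east) / 2
        cy = (f.extent.south + f.extent.north) / 2
        vals = f.c + f.amplitude * np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / (2 * f.width**2)
        ) + np.zeros((rows, cols))
    elif f.kind == "seeded_noise":
        rng = np.random.default_rng(np.uint64(f.seed) + np.uint64(step))
        vals = rng.normal(loc=f.c, scale=max(f.amplitude, 1e-12), size=(rows, cols))
    elif f.kind == "checkerboard":
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        vals = f.c + f.amplitude * ((rr + cc) % 2)
    else:  # pragma: no cover - guarded by Literal
        raise ParameterError(f"unknown field kind {f.kind!r}")
    return vals.astype(np.float64), t


def make_raster_fixture(f: FixtureField) -> RasterGrid:
    """Deterministic single-band raster realising the field recipe."""
    vals, t = _field_values(f)
    return RasterGrid(vals, t, f.crs_id, f.nodata)


def make_cube_fixture(
    f: FixtureField, years: Sequence[int | str], steps_per_year: int = 12
) -> GridCube:
    """Deterministic (time, y, x) cube; per-step fields keyed by (seed, step)."""
    if not years:
        raise ParameterError("years must be non-empty")
    if steps_per_year < 1:
        raise ParameterError(f"steps_per_year must be >= 1, got {steps_per_year}")
    step_seconds = (365 * 24 * 3600) // steps_per_year
    times = []
    slabs = []
    step = 0
    for year in sorted(int(y) for y in years):
        start = np.datetime64(f"{year:04d}-01-01", "s")
        for s in range(steps_per_year):
            times.append(start + np.timedelta64(s * step_seconds, "s"))
            vals, t = _field_values(f, step=step)
            slabs.append(vals)
            step += 1
    return GridCube(np.stack(slabs), np.array(times), t, f.crs_id, f.nodata)


def make_participants_fixture(
    n: int, bbox: BoundingBox, seed: int = 0, out_of_bounds_fraction: float = 0.0
) -> ParticipantTable:
    """Uniform points in the box, with a fixed fraction placed just outside.

    Out-of-bounds points sit a fixed small offset east of the box so the
    unmatched count in linkage tests is exactly reproducible.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not (0 <= out_of_bounds_fraction < 1):
        raise ParameterError("out_of_bounds_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_in = math.ceil(n * (1 - out_of_bounds_fraction))
    lons = rng.uniform(bbox.west, bbox.east, size=n)
    lats = rng.uniform(bbox.south, bbox.north, size=n)
    margin = 0.1 * (bbox.east - bbox.west)
    lons[n_in:] = min(bbox.east + margin, 180.0)
    ids = [f"S{i + 1:06d}" for i in range(n)]
    return make_participants(ids, lons, lats)


def populate_fixture_provider(
    root: str | os.PathLike,
    sources: Sequence[SourceSpec],
    years: Sequence[str],
    fields: dict[tuple[str, str], FixtureField],
    steps_per_year: int = 12,
    tiled: int = 1,
    skip: set[tuple[str, str, str]] = frozenset(),
) -> list[str]:
    """Write a directory tree the fixture provider can serve.

    ``fields`` maps (source_id, variable) to a field recipe; ``tiled``
    splits GeoTIFF fixtures into that many vertical strips under a
    ``tiles/`` directory (stitching them back reproduces the untiled
    field exactly); ``skip`` keys are omitted to drive failure/resume
    tests.
    """
    import pandas as pd

    root = Path(root)
    written: list[str] = []
    for src in sources:
        for var in src.variables:
            f = fields[(src.source_id, var.name)]
            year_tags = ["static"] if src.is_static else [str(y) for y in years]
            for tag in year_tags:
                if (src.source_id, var.name, tag) in skip:
                    continue
                path = Path(dataset_path(root, src.source_id, var.name, tag,
                                         src.storage_format))
                if src.storage_format == "geotiff":
                    grid = make_raster_fixture(f)
                    if tiled > 1:
                        tiles_dir = path.parent / "tiles"
                        cols = grid.shape[1]
                        edges = np.linspace(0, cols, tiled + 1).astype(int)
                        for i, (c0, c1) in enumerate(zip(edges[:-1], edges[1:])):
                            t = grid.transform
                            sub = RasterGrid(
                                grid.values[:, c0:c1].copy(),
                                GridTransform(t.x_origin + c0 * t.x_size, t.y_origin,
                                              t.x_size, t.y_size),
                                grid.crs_id, grid.nodata,
                            )
                            tile_path = tiles_dir / f"{path.stem}_tile{i}.tif"
                            write_raster(sub, tile_path)
                            written.append(str(tile_path))
                    else:
                        write_raster(grid, path)
                        written.append(str(path))
                elif src.storage_format == "netcdf":
                    cube = make_cube_fixture(
                        f, [int(tag)] if tag != "static" else [2000], steps_per_year
                    )
                    cube.variable = var.name
                    write_cube(cube, path)
                    written.append(str(path))
                else:
                    table = pd.DataFrame(
                        {"region": ["R1", "R2"], var.name: [f.c, f.c + f.amplitude]}
                    )
                    write_table(table, path)
                    written.append(str(path))
    return written


def write_complete_layer(store_root: str | os.PathLike, source_id: str, variable: str,
                         year: str, layer) -> str:
    """Convenience: write a raster/cube into a store and mark it complete."""
    fmt = "geotiff" if isinstance(layer, RasterGrid) else "netcdf"
    path = dataset_path(store_root, source_id, variable, year, fmt)
    if isinstance(layer, RasterGrid):
        write_raster(layer, path)
    else:
        write_cube(layer, path)
    write_sentinel(path)
    return path
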