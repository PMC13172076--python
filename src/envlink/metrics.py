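"""Neighbourhood raster metrics and terrain derivatives.

Focal statistics (mean, standard deviation, variance) are computed over a
circular kernel of user-defined radius: a cell's neighbourhood is every
cell whose center lies within ``radius_px`` pixels of it (Euclidean
distance in index space). Windows shrink at raster borders and around
nodata cells — the statistic is taken over whatever valid cells remain,
so outputs stay defined near edges without inventing data; a cell with no
valid neighbour at all becomes nodata. Variance is the population
variance (n divisor): these are texture filters, not inferential
estimates.

Slope and aspect come from second-order central differences on the four
rook neighbours of each interior cell (the Zevenbergen–Thorne scheme):
``p = (z_E - z_W) / 2g`` and ``q = (z_N - z_S) / 2g`` estimate the
east-west and south-north gradients, slope is ``atan(sqrt(p^2 + q^2))``
and aspect is the compass bearing of the downslope vector ``(-p, -q)``,
degrees clockwise from north. The scheme reproduces planar surfaces
exactly. Flat cells have undefined aspect and map to nodata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ParameterError
from .grids import GridTransform, RasterGrid

METERS_PER_DEGREE = 111320.0

FocalMetric = Literal["mean", "sd", "variance"]


@dataclass(frozen=True)
class KernelSpec:
    radius_px: float
    metric: FocalMetric

    def __post_init__(self) -> None:
        if self.radius_px < 0:
            raise ParameterError(f"kernel radius must be >= 0, got {self.radius_px}")


def make_circular_kernel(radius_px: float) -> list[tuple[int, int]]:
    """Offsets (dr, dc) with Euclidean norm <= radius_px, sorted."""
    if radius_px < 0:
        raise ParameterError(f"kernel radius must be >= 0, got {radius_px}")
    r = int(math.floor(radius_px))
    offsets = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if math.sqrt(dr * dr + dc * dc) <= radius_px
    ]
    return sorted(offsets)


def radius_to_pixels(radius_m: float, grid: RasterGrid) -> float:
    """Convert a metric radius to pixels on a projected or geographic grid.

    Projected (meter) grids divide by the pixel size directly; geographic
    grids use the north-south pixel size at 111320 m per degree.
    """
    if radius_m < 0:
        raise ParameterError(f"radius must be >= 0, got {radius_m}")
    if _is_geographic(grid.crs_id):
        return radius_m / (METERS_PER_DEGREE * grid.transform.y_size)
    return radius_m / grid.transform.x_size


def _is_geographic(crs_id: str) -> bool:
    c = (crs_id or "").upper()
    return c in ("EPSG:4326", "WGS84", "CRS:84") or c.startswith("GEOGRAPHIC")


def focal_stat(grid: RasterGrid, kernel: KernelSpec) -> RasterGrid:
    """Focal mean / sd / variance under a circular kernel.

    Accumulates shifted copies of the valid-masked grid offset by offset
    (in the sorted kernel order, so results are reproducible to the bit),
    then forms the statistic from the running count, sum and sum of
    squares.
    """
    offsets = make_circular_kernel(kernel.radius_px)
    values = np.asarray(grid.values, dtype=np.float64)
    valid = grid.valid_mask()
    vals0 = np.where(valid, values, 0.0)
    rows, cols = values.shape
    count = np.zeros((rows, cols), dtype=np.float64)
    total = np.zeros((rows, cols), dtype=np.float64)
    total_sq = np.zeros((rows, cols), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        dst = (slice(r0, r1), slice(c0, c1))
        count[dst] += valid[src]
        total[dst] += vals0[src]
        total_sq[dst] += vals0[src] * vals0[src]
    nodata = grid.nodata if grid.nodata is not None else float(np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
        if kernel.metric == "mean":
            out = mean
        else:
            variance = total_sq / count - mean * mean
            variance = np.maximum(variance, 0.0)  # guard tiny negative round-off
            out = np.sqrt(variance) if kernel.metric == "sd" else variance
    out = np.where(count > 0, out, nodata)
    return RasterGrid(out, grid.transform, grid.crs_id, grid.nodata)


def cell_size_meters(grid: RasterGrid) -> float:
    """Physical cell size used for terrain derivatives.

    Geographic grids derive it from the north-south pixel size; projected
    grids use the pixel size as-is (assumed meters).
    """
    if _is_geographic(grid.crs_id):
        return METERS_PER_DEGREE * grid.transform.y_size
    return grid.transform.x_size


def slope_aspect(
    dem: RasterGrid, cell_size_m: float | None = None
) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and aspect (degrees clockwise from north) of a DEM.

    Border cells and cells with any nodata rook neighbour are nodata in
    both outputs; flat cells are nodata in aspect only.
    """
    if cell_size_m is None:
        cell_size_m = cell_size_meters(dem)
    if cell_size_m <= 0:
        raise ParameterError(f"cell size must be > 0, got {cell_size_m}")
    z = np.asarray(dem.values, dtype=np.float64)
    rows, cols = z.shape
    if rows < 3 or cols < 3:
        raise ParameterError("DEM must be at least 3x3 for terrain derivatives")
    valid = dem.valid_mask()
    nodata = dem.nodata if dem.nodata is not None else float(np.nan)

    slope = np.full_like(z, nodata)
    aspect = np.full_like(z, nodata)

    interior = (slice(1, -1), slice(1, -1))
    ok = (
        valid[interior]
        & valid[:-2, 1:-1]  # north
        & valid[2:, 1:-1]   # south
        & valid[1:-1, 2:]   # east
        & valid[1:-1, :-2]  # west
    )
    g2 = 2.0 * cell_size_m
    p = (z[1:-1, 2:] - z[1:-1, :-2]) / g2       # east-west gradient
    q = (z[:-2, 1:-1] - z[2:, 1:-1]) / g2       # south-north gradient (row 0 is north)
    slope_deg = np.degrees(np.arctan(np.hypot(p, q)))
    aspect_deg = np.degrees(np.arctan2(-p, -q)) % 360.0
    flat = (p == 0) & (q == 0)

    slope[interior] = np.where(ok, slope_deg, nodata)
    aspect[interior] = np.where(ok & ~flat, aspect_deg, nodata)
    return (
        RasterGrid(slope, dem.transform, dem.crs_id, dem.nodata),
        RasterGrid(aspect, dem.transform, dem.crs_id, dem.nodata),
    )


def metric_output_name(variable: str, metric: str, radius_m: float | None) -> str:
    """File stem for a derived metric layer, e.g. ``elevation_mean_r500m``."""
    if radius_m is None:
        return f"{variable}_{metric}"
    r = int(radius_m) if float(radius_m).is_integer() else radius_m
    return f"{variable}_{metric}_r{r}m"
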