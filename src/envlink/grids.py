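"""In-memory raster containers.

A :class:`RasterGrid` is a single-band 2-D grid with an affine
geotransform; a :class:`GridCube` adds a leading time axis. The transform
origin is the *outer corner* of the top-left pixel and cells are half-open
``[x, x+dx) x (y-dy, y]`` with the row index increasing southward, which
fixes all sampling and subsetting arithmetic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class GridTransform:
    """Affine relation between (row, col) indices and CRS coordinates.

    ``x_origin``/``y_origin`` locate the outer corner of the top-left
    pixel; ``x_size``/``y_size`` are positive pixel sizes in CRS units,
    with y decreasing as the row index grows (north-up grids).
    """

    x_origin: float
    y_origin: float
    x_size: float
    y_size: float

    def __post_init__(self) -> None:
        if not (self.x_size > 0 and self.y_size > 0):
            raise ValidationError("pixel sizes must be positive")

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.x_size,
            self.y_origin - (row + 0.5) * self.y_size,
        )

    def x_centers(self, ncols: int) -> np.ndarray:
        return self.x_origin + (np.arange(ncols) + 0.5) * self.x_size

    def y_centers(self, nrows: int) -> np.ndarray:
        return self.y_origin - (np.arange(nrows) + 0.5) * self.y_size


@dataclass
class RasterGrid:
    """Single-band raster: values + geotransform + CRS id + nodata sentinel."""

    values: np.ndarray
    transform: GridTransform
    crs_id: str = "EPSG:4326"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValidationError("raster values must be a non-empty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data (not nodata, not NaN)."""
        m = ~np.isnan(self.values) if np.issubdtype(self.values.dtype, np.floating) else np.ones(self.values.shape, bool)
        if self.nodata is not None:
            m &= self.values != self.nodata
        return m

    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds of the grid."""
        rows, cols = self.shape
        t = self.transform
        return (
            t.x_origin,
            t.y_origin - rows * t.y_size,
            t.x_origin + cols * t.x_size,
            t.y_origin,
        )

    def equals(self, other: "RasterGrid") -> bool:
        return (
            self.crs_id == other.crs_id
            and self.transform == other.transform
            and _same_nodata(self.nodata, other.nodata)
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class GridCube:
    """(time, y, x) stack sharing one geotransform; times strictly increasing."""

    values: np.ndarray
    times: np.ndarray  # datetime64
    transform: GridTransform
    crs_id: str = "EPSG:4326"
    nodata: float | None = None
    variable: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        if self.values.ndim != 3:
            raise ValidationError("cube values must be 3-D (time, y, x)")
        if len(self.times) != self.values.shape[0]:
            raise ValidationError("time coordinate length must match the time axis")
        if len(self.times) > 1 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValidationError("times must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def equals(self, other: "GridCube") -> bool:
        return (
            self.crs_id == other.crs_id
            and self.transform == other.transform
            and _same_nodata(self.nodata, other.nodata)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def _same_nodata(a: float | None, b: float | None) -> bool:
    if a is None or b is None:
        return a is b
    return float(a) == float(b)
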