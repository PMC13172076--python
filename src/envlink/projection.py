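"""Coordinate transformations for linkage.

Participant coordinates arrive in geographic WGS84 and are transformed
into each raster layer's native CRS before sampling, so large rasters are
never resampled. Two projections are built in: the identity (geographic
layers) and the spherical sinusoidal equal-area projection used by MODIS
vegetation products,

    x = R * lambda * cos(phi),   y = R * phi

with longitude/latitude in radians and R the MODIS authalic sphere radius
(6,371,007.181 m) by default. The sinusoidal forward map has the exact
analytic inverse ``phi = y / R``, ``lambda = x / (R cos phi)``. Any other
CRS is delegated to a user-registered projection engine.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Literal

import numpy as np

from .errors import ProjectionError, ValidationError

MODIS_SPHERE_RADIUS_M = 6_371_007.181

_SINUSOIDAL_RE = re.compile(r"^SINUSOIDAL(?::R=(?P<radius>[0-9.]+))?$", re.IGNORECASE)
_GEOGRAPHIC_IDS = {"EPSG:4326", "WGS84", "CRS:84"}

# registry of engines for CRSs the package does not project itself:
# crs_id -> (forward, inverse), each mapping (lon, lat) arrays to (x, y) arrays
_ENGINES: dict[str, tuple[Callable, Callable]] = {}


def register_projection_engine(crs_id: str, forward: Callable, inverse: Callable) -> None:
    _ENGINES[crs_id.upper()] = (forward, inverse)


@dataclass(frozen=True)
class ProjectionSpec:
    crs_id: str
    kind: Literal["geographic_wgs84", "sinusoidal_sphere", "external"]
    sphere_radius_m: float = MODIS_SPHERE_RADIUS_M

    def __post_init__(self) -> None:
        if self.kind == "sinusoidal_sphere" and not self.sphere_radius_m > 0:
            raise ValidationError("sinusoidal sphere radius must be positive")

    @classmethod
    def from_crs_id(cls, crs_id: str) -> "ProjectionSpec":
        cid = (crs_id or "").strip()
        if cid.upper() in _GEOGRAPHIC_IDS:
            return cls(cid, "geographic_wgs84")
        m = _SINUSOIDAL_RE.match(cid)
        if m:
            radius = float(m.group("radius")) if m.group("radius") else MODIS_SPHERE_RADIUS_M
            return cls(cid, "sinusoidal_sphere", radius)
        return cls(cid, "external")


def transform_points(
    points: Iterable[tuple[float, float]], target: ProjectionSpec
) -> list[tuple[float, float]]:
    """Project WGS84 (lon, lat) pairs into the target CRS."""
    pts = list(points)
    if not pts:
        return []
    lon = np.array([p[0] for p in pts], dtype=np.float64)
    lat = np.array([p[1] for p in pts], dtype=np.float64)
    if target.kind == "geographic_wgs84":
        x, y = lon, lat
    elif target.kind == "sinusoidal_sphere":
        x, y = sinusoidal_forward(lon, lat, target.sphere_radius_m)
    else:
        engine = _ENGINES.get(target.crs_id.upper())
        if engine is None:
            raise ProjectionError(
                f"no projection engine registered for CRS {target.crs_id!r}"
            )
        x, y = engine[0](lon, lat)
    return list(zip(np.asarray(x, float).tolist(), np.asarray(y, float).tolist()))


def inverse_transform_points(
    points: Iterable[tuple[float, float]], source: ProjectionSpec
) -> list[tuple[float, float]]:
    """Map native-CRS (x, y) pairs back to WGS84 (lon, lat)."""
    pts = list(points)
    if not pts:
        return []
    x = np.array([p[0] for p in pts], dtype=np.float64)
    y = np.array([p[1] for p in pts], dtype=np.float64)
    if source.kind == "geographic_wgs84":
        lon, lat = x, y
    elif source.kind == "sinusoidal_sphere":
        lon, lat = sinusoidal_inverse(x, y, source.sphere_radius_m)
    else:
        engine = _ENGINES.get(source.crs_id.upper())
        if engine is None:
            raise ProjectionError(
                f"no projection engine registered for CRS {source.crs_id!r}"
            )
        lon, lat = engine[1](x, y)
    return list(zip(np.asarray(lon, float).tolist(), np.asarray(lat, float).tolist()))


def sinusoidal_forward(
    lon_deg: np.ndarray, lat_deg: np.ndarray, radius_m: float = MODIS_SPHERE_RADIUS_M
) -> tuple[np.ndarray, np.ndarray]:
    lam = np.radians(np.asarray(lon_deg, np.float64))
    phi = np.radians(np.asarray(lat_deg, np.float64))
    return radius_m * lam * np.cos(phi), radius_m * phi


def sinusoidal_inverse(
    x: np.ndarray, y: np.ndarray, radius_m: float = MODIS_SPHERE_RADIUS_M
) -> tuple[np.ndarray, np.ndarray]:
    phi = np.asarray(y, np.float64) / radius_m
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.asarray(x, np.float64) / (radius_m * np.cos(phi))
    lam = np.where(np.asarray(x) == 0, 0.0, lam)  # poles: cos(phi)=0, lon undefined
    return np.degrees(lam), np.degrees(phi)
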