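"""Workflow configuration, source catalogue and job planning.

Three JSON documents drive a database build: the global workflow config
(storage folders, years, named area), a bounding-box registry mapping area
keys to ``[north, west, south, east]`` arrays, and one spec per data source
(access kind, format, native CRS, coverage, available years, variables and
optional neighbourhood metrics). :func:`plan_jobs` crosses them into a flat
list of (source, variable, year) materialization jobs, applying the year-
and region-availability filters, and is the unit the incremental runner
consumes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import ConfigurationError, FormatError, LookupError_, ValidationError

Metric = Literal["mean", "sd", "variance", "slope", "aspect"]
KERNEL_METRICS = {"mean", "sd", "variance"}
TERRAIN_METRICS = {"slope", "aspect"}

_IDENT_RE = re.compile(r"^[A-Za-z0-9_-]+$")


# ---------------------------------------------------------------------------
# bounding boxes


@dataclass(frozen=True)
class BoundingBox:
    """Rectangular geographic extent; element order is [N, W, S, E]."""

    north: float
    west: float
    south: float
    east: float

    def __post_init__(self) -> None:
        if not (-90 <= self.south < self.north <= 90):
            raise ValidationError(
                f"latitudes must satisfy -90 <= south < north <= 90, "
                f"got south={self.south}, north={self.north}"
            )
        if not (-180 <= self.west < self.east <= 180):
            raise ValidationError(
                f"longitudes must satisfy -180 <= west < east <= 180 "
                f"(antimeridian-crossing boxes rejected), "
                f"got west={self.west}, east={self.east}"
            )

    def as_list(self) -> list[float]:
        return [self.north, self.west, self.south, self.east]

    def contains(self, lon: float, lat: float) -> bool:
        return self.west <= lon <= self.east and self.south <= lat <= self.north

    def intersects(self, other: "BoundingBox") -> bool:
        # zero-area (edge-touching) overlaps contain no pixel centers
        return (
            self.west < other.east
            and other.west < self.east
            and self.south < other.north
            and other.south < self.north
        )


@dataclass
class AreaRegistry:
    entries: dict[str, BoundingBox]

    def keys(self) -> list[str]:
        return list(self.entries)

    def as_json(self) -> str:
        return json.dumps({k: v.as_list() for k, v in self.entries.items()})


def _loads(text: str):
    # registries in the wild print U+2212 minus signs; normalize before parsing
    try:
        return json.loads(text.replace("−", "-"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc


def parse_area_registry(text: str) -> AreaRegistry:
    """Parse a ``{"name": [north, west, south, east], ...}`` registry."""
    doc = _loads(text)
    if not isinstance(doc, dict):
        raise FormatError("area registry must be a JSON object")
    entries: dict[str, BoundingBox] = {}
    for key, arr in doc.items():
        if not isinstance(arr, (list, tuple)) or len(arr) != 4:
            raise FormatError(f"area {key!r}: expected a 4-number array, got {arr!r}")
        try:
            entries[key] = BoundingBox(*(float(v) for v in arr))
        except ValidationError as exc:
            raise ValidationError(f"area {key!r}: {exc}") from exc
    return AreaRegistry(entries)


def resolve_area(registry: AreaRegistry, key: str) -> BoundingBox:
    try:
        return registry.entries[key]
    except KeyError:
        raise LookupError_(
            f"unknown area {key!r}; available areas: {sorted(registry.entries)}"
        ) from None


# ---------------------------------------------------------------------------
# workflow config


@dataclass
class WorkflowConfig:
    download_folder: str
    tmp_folder: str
    configs_assets_folder: str
    secrets_folder: str
    years: list[str]
    update_years: list[str]
    area: str
    extras: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def as_json(self) -> str:
        doc = {
            "download_folder": self.download_folder,
            "tmp_folder": self.tmp_folder,
            "configs_assets_folder": self.configs_assets_folder,
            "secrets_folder": self.secrets_folder,
            "years": self.years,
            "update_years": self.update_years,
            "area": self.area,
        }
        doc.update(self.extras)
        return json.dumps(doc)


_REQUIRED_CONFIG_KEYS = (
    "download_folder",
    "tmp_folder",
    "configs_assets_folder",
    "secrets_folder",
    "years",
    "area",
)


def _normalize_years(raw, key: str) -> list[str]:
    if not isinstance(raw, list):
        raise ConfigurationError(f"{key!r} must be a list of years")
    out = []
    for y in raw:
        try:
            out.append(str(int(str(y))))
        except ValueError:
            raise ConfigurationError(f"{key!r} entry {y!r} does not parse as a year") from None
    return out


def parse_workflow_config(text: str) -> WorkflowConfig:
    """Parse and validate the global workflow configuration JSON."""
    doc = _loads(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("workflow config must be a JSON object")
    for key in _REQUIRED_CONFIG_KEYS:
        if key not in doc:
            raise ConfigurationError(f"missing required key {key!r}")
    years = _normalize_years(doc["years"], "years")
    if not years:
        raise ConfigurationError("years must be non-empty")
    update_years = _normalize_years(doc.get("update_years", []), "update_years")
    known = set(_REQUIRED_CONFIG_KEYS) | {"update_years"}
    extras = {k: v for k, v in doc.items() if k not in known}
    warnings = [f"unknown configuration key {k!r}" for k in extras]
    return WorkflowConfig(
        download_folder=str(doc["download_folder"]),
        tmp_folder=str(doc["tmp_folder"]),
        configs_assets_folder=str(doc["configs_assets_folder"]),
        secrets_folder=str(doc["secrets_folder"]),
        years=years,
        update_years=update_years,
        area=str(doc["area"]),
        extras=extras,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# source specs


@dataclass
class VariableSpec:
    name: str
    units: str = ""
    neighbourhood_metrics: list[tuple[Metric, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for metric, radius in self.neighbourhood_metrics:
            if metric in KERNEL_METRICS:
                if radius is None or radius <= 0:
                    raise ValidationError(
                        f"variable {self.name!r}: metric {metric!r} requires radius_m > 0, "
                        f"got {radius!r}"
                    )
            elif metric in TERRAIN_METRICS:
                if radius is not None:
                    raise ValidationError(
                        f"variable {self.name!r}: terrain metric {metric!r} carries no radius"
                    )
            else:
                raise ValidationError(f"variable {self.name!r}: unknown metric {metric!r}")


@dataclass
class SourceSpec:
    source_id: str
    access_kind: Literal["direct", "api", "fixture"]
    url: str
    temporal_resolution: Literal["static", "yearly", "daily", "hourly"]
    storage_format: Literal["geotiff", "netcdf", "csv"]
    native_crs: str
    coverage: BoundingBox | Literal["global"]
    available_years: set[str] | Literal["all"]
    variables: list[VariableSpec]

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValidationError(f"source {self.source_id!r}: variables must be non-empty")

    @property
    def is_static(self) -> bool:
        return self.temporal_resolution == "static"

    def as_json(self) -> str:
        doc = {
            "source_id": self.source_id,
            "access_kind": self.access_kind,
            "url": self.url,
            "temporal_resolution": self.temporal_resolution,
            "storage_format": self.storage_format,
            "native_crs": self.native_crs,
            "coverage": "global" if self.coverage == "global" else self.coverage.as_list(),
            "available_years": (
                "all" if self.available_years == "all" else sorted(self.available_years)
            ),
            "variables": [
                {
                    "name": v.name,
                    "units": v.units,
                    "neighbourhood_metrics": [
                        {"metric": m, "radius_m": r} for m, r in v.neighbourhood_metrics
                    ],
                }
                for v in self.variables
            ],
        }
        return json.dumps(doc)


def parse_source_spec(text: str) -> SourceSpec:
    """Parse a per-source configuration JSON document."""
    doc = _loads(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("source spec must be a JSON object")
    for key in ("source_id", "access_kind", "url", "temporal_resolution",
                "storage_format", "native_crs", "variables"):
        if key not in doc:
            raise ConfigurationError(f"missing required key {key!r}")
    cov_raw = doc.get("coverage", "global")
    coverage: BoundingBox | str
    if cov_raw == "global":
        coverage = "global"
    else:
        if not isinstance(cov_raw, (list, tuple)) or len(cov_raw) != 4:
            raise FormatError(f"coverage must be 'global' or a 4-number array, got {cov_raw!r}")
        coverage = BoundingBox(*(float(v) for v in cov_raw))
    years_raw = doc.get("available_years", "all")
    available: set[str] | str
    if years_raw == "all":
        available = "all"
    else:
        available = set(_normalize_years(list(years_raw), "available_years"))
    variables = []
    for v in doc["variables"]:
        if isinstance(v, str):
            variables.append(VariableSpec(name=v))
            continue
        metrics = [
            (m["metric"], m.get("radius_m"))
            for m in v.get("neighbourhood_metrics", [])
        ]
        variables.append(
            VariableSpec(name=v["name"], units=v.get("units", ""),
                         neighbourhood_metrics=metrics)
        )
    if not variables:
        raise ValidationError(f"source {doc['source_id']!r}: variables must be non-empty")
    return SourceSpec(
        source_id=str(doc["source_id"]),
        access_kind=doc["access_kind"],
        url=str(doc["url"]),
        temporal_resolution=doc["temporal_resolution"],
        storage_format=doc["storage_format"],
        native_crs=str(doc["native_crs"]),
        coverage=coverage,  # type: ignore[arg-type]
        available_years=available,  # type: ignore[arg-type]
        variables=variables,
    )


# ---------------------------------------------------------------------------
# job planning

STATIC_TAG = "static"


@dataclass
class Job:
    source_id: str
    variable: str
    year: str  # a 4-digit year or the literal "static"
    target: str
    status: Literal["pending", "complete", "incomplete"] = "pending"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_id, self.variable, self.year)


@dataclass
class JobPlan:
    jobs: list[Job]
    warnings: list[str] = field(default_factory=list)

    def pending(self) -> list[Job]:
        return [j for j in self.jobs if j.status != "complete"]


def plan_jobs(
    config: WorkflowConfig,
    sources: Sequence[SourceSpec],
    registry: AreaRegistry,
    update_mode: bool = False,
    complete_paths: Iterable[str] = (),
) -> JobPlan:
    """Cross config x sources into the materialization job list.

    Years are restricted to the intersection of the requested years (or
    ``update_years`` in update mode) with each source's available years;
    sources whose coverage box is disjoint from the resolved area are
    dropped with a warning. ``complete_paths`` (relative store paths, e.g.
    from a store manifest) marks already-built outputs complete.
    """
    from .store import dataset_path  # local import: store depends on config types

    area = resolve_area(registry, config.area)
    wanted_years = config.update_years if update_mode else config.years
    done = set(complete_paths)
    jobs: list[Job] = []
    warnings: list[str] = []
    for src in sources:
        if src.coverage != "global" and not area.intersects(src.coverage):
            warnings.append(
                f"source {src.source_id!r} skipped: coverage does not include "
                f"area {config.area!r}"
            )
            continue
        if src.is_static:
            years = [STATIC_TAG]
        else:
            if src.available_years == "all":
                years = sorted(set(wanted_years), key=int)
            else:
                years = sorted(set(wanted_years) & set(src.available_years), key=int)
            if not years:
                warnings.append(
                    f"source {src.source_id!r} skipped: none of the requested years "
                    f"{sorted(set(wanted_years), key=int)} are available "
                    f"(available: {sorted(src.available_years, key=int)})"
                )
                continue
        for var in src.variables:
            for year in years:
                rel = dataset_path("", src.source_id, var.name, year, src.storage_format)
                status = "complete" if rel in done else "pending"
                jobs.append(Job(src.source_id, var.name, year, rel, status))
    return JobPlan(jobs=jobs, warnings=warnings)
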