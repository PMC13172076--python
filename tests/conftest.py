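import json

import numpy as np
import pytest

from envlink import (
    BoundingBox,
    FixtureField,
    GridTransform,
    RasterGrid,
    parse_area_registry,
    parse_source_spec,
    parse_workflow_config,
)

# Registry of named areas with [north, west, south, east] entries; the text
# deliberately uses U+2212 minus signs, which real-world listings print.
REGISTRY_TEXT = (
    '{"Europe": [72, −15, 30, 42.5],'
    '"UK": [60.8608, −8.6493, 49.9096, 1.7689],'
    '"Brandenburg": [53.5587, 11.2682, 51.3618, 14.7636],'
    '"Berlin": [52.7136,12.9673,52.2839,13.816]}'
)

BERLIN_BOX = BoundingBox(north=52.7136, west=12.9673, south=52.2839, east=13.816)


@pytest.fixture
def registry():
    return parse_area_registry(REGISTRY_TEXT)


@pytest.fixture
def workflow_config_doc(tmp_path):
    return {
        "download_folder": str(tmp_path / "db"),
        "tmp_folder": str(tmp_path / "tmp"),
        "configs_assets_folder": str(tmp_path / "cfg"),
        "secrets_folder": str(tmp_path / "secrets"),
        "years": ["2022", "2023", "2024", "2025"],
        "update_years": ["2025"],
        "area": "Berlin",
    }


@pytest.fixture
def workflow_config(workflow_config_doc):
    return parse_workflow_config(json.dumps(workflow_config_doc))


def source_doc(source_id="dem", fmt="geotiff", url="", temporal="static",
               coverage="global", years="all", variables=None):
    return {
        "source_id": source_id,
        "access_kind": "fixture",
        "url": url,
        "temporal_resolution": temporal,
        "storage_format": fmt,
        "native_crs": "EPSG:4326",
        "coverage": coverage,
        "available_years": years,
        "variables": variables or [{"name": "elevation"}],
    }


@pytest.fixture
def dem_source(tmp_path):
    return parse_source_spec(json.dumps(source_doc(url=str(tmp_path / "fix"))))


def small_grid(values, x0=0.0, y0=None, size=1.0, crs="EPSG:32633", nodata=-9999.0):
    values = np.asarray(values, dtype=np.float64)
    if y0 is None:
        y0 = values.shape[0] * size
    return RasterGrid(values, GridTransform(x0, y0, size, size), crs, nodata)


def random_grid(rng, rows=64, cols=64, nodata_frac=0.1, nodata=-9999.0):
    vals = rng.normal(size=(rows, cols))
    mask = rng.random((rows, cols)) < nodata_frac
    vals[mask] = nodata
    return small_grid(vals, nodata=nodata)


@pytest.fixture
def plane_field():
    return FixtureField(kind="plane", a=100.0, b=50.0, c=5.0)
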