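"""Participant linkage: sampling, grouping, routes and privacy utilities."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envlink import (
    BoundingBox,
    GridCube,
    GridTransform,
    RasterGrid,
    jitter_coordinates,
    link_cube,
    link_rasters,
    link_route,
    make_participants,
    read_locations,
    sample_raster,
    snap_to_grid,
)
from envlink.errors import FormatError, ValidationError
from envlink.fixtures import write_complete_layer
from envlink.linkage import layer_column_name, point_to_pixel
from envlink.metrics import METERS_PER_DEGREE
from envlink.store import write_raster

from conftest import small_grid


def geo_grid(values, west=13.0, north=52.6, size=0.1, nodata=-9999.0):
    return RasterGrid(np.asarray(values, float),
                      GridTransform(west, north, size, size), "EPSG:4326", nodata)


class TestReadLocations:
    def test_minimal_three_columns(self, tmp_path):
        path = tmp_path / "loc.csv"
        path.write_text("ID,Longitude,Latitude\nA,13.1,52.4\nB,13.2,52.5\n")
        table = read_locations(path)
        assert len(table) == 2
        assert table.subject_ids == ["A", "B"]

    def test_missing_latitude_named(self, tmp_path):
        path = tmp_path / "loc.csv"
        path.write_text("id,longitude\nA,13.1\n")
        with pytest.raises(FormatError, match="latitude"):
            read_locations(path)

    def test_out_of_range_latitude_cites_row(self, tmp_path):
        rows = "".join(f"S{i},13.0,{50 + i}\n" for i in range(6))
        path = tmp_path / "loc.csv"
        path.write_text("id,lon,lat\n" + rows + "S7,13.0,95\n")
        with pytest.raises(ValidationError, match="row 7"):
            read_locations(path)

    def test_duplicate_subject_rejected(self, tmp_path):
        path = tmp_path / "loc.csv"
        path.write_text("id,lon,lat\nA,13.1,52.4\nA,13.2,52.5\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_locations(path)

    def test_route_columns_allow_repeats(self, tmp_path):
        path = tmp_path / "loc.csv"
        path.write_text(
            "id,lon,lat,route_id,sequence\nA,13.1,52.4,r1,0\nA,13.2,52.5,r1,1\n"
        )
        table = read_locations(path)
        assert table.route_ids == ["r1", "r1"]
        assert table.sequences == [0, 1]


class TestSampleRaster:
    def test_pixel_center_hits_its_pixel(self):
        grid = small_grid(np.arange(16.0).reshape(4, 4))
        assert sample_raster(grid, [(2.5, 1.5)]) == [grid.values[2, 2]]

    def test_outside_extent_is_null(self):
        grid = small_grid(np.ones((2, 2)))
        assert sample_raster(grid, [(-1.0, 0.5), (0.5, 99.0)]) == [None, None]

    def test_nodata_cell_is_null(self):
        vals = np.ones((2, 2))
        vals[0, 0] = -9999.0
        grid = small_grid(vals)
        assert sample_raster(grid, [(0.5, 1.5)]) == [None]

    def test_matches_brute_force_containment(self):
        rng = np.random.default_rng(5)
        grid = small_grid(rng.normal(size=(13, 17)), x0=-3.0, size=0.5)
        pts = list(zip(rng.uniform(-5, 7, 100), rng.uniform(-2, 9, 100)))
        got = sample_raster(grid, pts)
        t = grid.transform
        for (x, y), v in zip(pts, got):
            hit = None
            for r in range(13):
                for c in range(17):
                    x0 = t.x_origin + c * t.x_size
                    y1 = t.y_origin - r * t.y_size
                    if x0 <= x < x0 + t.x_size and y1 - t.y_size < y <= y1:
                        hit = float(grid.values[r, c])
            assert v == hit

    def test_resolution_consistency_under_2x_upsampling(self):
        rng = np.random.default_rng(9)
        grid = small_grid(rng.normal(size=(8, 8)))
        up = small_grid(np.kron(grid.values, np.ones((2, 2))), size=0.5)
        pts = list(zip(rng.uniform(0, 8, 200), rng.uniform(0, 8, 200)))
        assert sample_raster(grid, pts) == sample_raster(up, pts)


class TestLinkRasters:
    def _store(self, tmp_path, grid):
        write_complete_layer(tmp_path / "db", "dem", "elevation", "static", grid)
        return tmp_path / "db"

    def test_one_csv_per_layer_row_order_preserved(self, tmp_path):
        root = self._store(tmp_path, geo_grid(np.arange(36.0).reshape(6, 6)))
        parts = make_participants(["B", "A"], [13.15, 13.35], [52.55, 52.35])
        written, warn = link_rasters(root, parts, tmp_path / "out")
        assert len(written) == 1 and warn == []
        df = pd.read_csv(written[0])
        assert list(df.columns) == ["subject_id", "dem__elevation__static"]
        assert df["subject_id"].tolist() == ["B", "A"]

    def test_subject_outside_extent_keeps_row_with_empty_field(self, tmp_path):
        root = self._store(tmp_path, geo_grid(np.ones((6, 6))))
        parts = make_participants(["in", "out"], [13.05, 0.0], [52.55, 0.0])
        written, _ = link_rasters(root, parts, tmp_path / "out")
        df = pd.read_csv(written[0])
        assert len(df) == 2
        assert df["dem__elevation__static"].isna().tolist() == [False, True]

    def test_incomplete_layer_skipped_with_warning(self, tmp_path):
        root = tmp_path / "db"
        write_raster(geo_grid(np.ones((4, 4))),
                     root / "dem" / "elevation" / "dem_elevation_static.tif")
        parts = make_participants(["A"], [13.05], [52.55])
        written, warn = link_rasters(root, parts, tmp_path / "out")
        assert written == []
        assert len(warn) == 1 and "incomplete" in warn[0]

    def test_column_name_for_derived_metric_layer(self):
        name = layer_column_name("root", "dem/elevation/elevation_mean_r500m.tif")
        assert name == "dem__elevation__elevation_mean_r500m"


def make_cube(rows=4, cols=4, steps=3, west=13.0, north=52.6, size=0.1, seed=0):
    rng = np.random.default_rng(seed)
    times = (np.datetime64("2023-01-01", "s")
             + np.arange(steps) * np.timedelta64(1, "D")).astype("datetime64[ns]")
    return GridCube(rng.normal(size=(steps, rows, cols)), times,
                    GridTransform(west, north, size, size), "EPSG:4326", -9999.0, "t2m")


class TestLinkCube:
    def test_all_subjects_one_pixel_one_group(self):
        cube = make_cube()
        parts = make_participants([f"S{i}" for i in range(5)],
                                  [13.01 + 0.001 * i for i in range(5)],
                                  [52.55] * 5)
        res = link_cube(cube, parts)
        assert len(res.groups) == 1
        assert sorted(res.groups[0].subjects) == sorted(parts.subject_ids)
        assert res.unmatched == []

    def test_distinct_pixels_distinct_groups(self):
        cube = make_cube()
        parts = make_participants(["a", "b", "c"], [13.05, 13.15, 13.25],
                                  [52.55, 52.45, 52.35])
        res = link_cube(cube, parts)
        assert len(res.groups) == 3

    def test_constructed_partition_three_one_offgrid(self):
        cube = make_cube()
        # 3 subjects share pixel A, 1 in pixel B, 1 outside the cube extent
        parts = make_participants(
            ["a1", "a2", "a3", "b", "off"],
            [13.01, 13.02, 13.03, 13.25, 0.0],
            [52.55, 52.56, 52.57, 52.45, 0.0],
        )
        res = link_cube(cube, parts)
        assert len(res.groups) == 2
        assert res.unmatched == ["off"]
        sizes = sorted(len(g.subjects) for g in res.groups)
        assert sizes == [1, 3]

    def test_partition_and_compression_properties_randomized(self):
        cube = make_cube(rows=20, cols=20, steps=2, size=0.01)
        rng = np.random.default_rng(77)
        n = 500
        parts = make_participants(
            [f"S{i}" for i in range(n)],
            rng.uniform(12.9, 13.3, n),  # some fall west of the cube
            rng.uniform(52.3, 52.7, n),
        )
        res = link_cube(cube, parts)
        grouped = [s for g in res.groups for s in g.subjects]
        assert sorted(grouped + res.unmatched) == sorted(parts.subject_ids)
        assert len(res.groups) <= min(n, 20 * 20)
        pixels = [tuple(g.pixel) for g in res.groups]
        assert len(set(pixels)) == len(pixels)

    def test_series_values_and_json_schema(self):
        cube = make_cube(steps=4)
        parts = make_participants(["s"], [13.05], [52.55])
        res = link_cube(cube, parts)
        (r, c) = res.groups[0].pixel
        assert res.groups[0].series == cube.values[:, r, c].tolist()
        doc = json.loads(res.to_json())
        assert set(doc) == {"variable", "crs", "time", "groups", "unmatched"}
        assert len(doc["time"]) == 4


class TestLinkRoute:
    def test_single_point_route(self):
        grid = geo_grid(np.arange(16.0).reshape(4, 4))
        summary = link_route([(13.05, 52.55)], grid)
        assert summary.mean == summary.min == summary.max == summary.values[0]

    def test_constant_grid_mean_is_constant(self):
        grid = geo_grid(np.full((4, 4), 3.5))
        summary = link_route([(13.05, 52.55), (13.15, 52.45), (13.35, 52.25)], grid)
        assert summary.mean == 3.5

    def test_matches_per_point_oracle(self):
        rng = np.random.default_rng(31)
        grid = geo_grid(rng.normal(size=(10, 10)), size=0.05)
        pts = list(zip(rng.uniform(12.9, 13.6, 10), rng.uniform(52.0, 52.7, 10)))
        summary = link_route(pts, grid)
        expected = sample_raster(grid, pts)
        assert summary.values == expected
        valid = [v for v in expected if v is not None]
        assert summary.mean == pytest.approx(np.mean(valid))
        assert summary.min == min(valid) and summary.max == max(valid)

    def test_all_null_route_has_null_summary(self):
        grid = geo_grid(np.ones((2, 2)))
        summary = link_route([(0.0, 0.0)], grid)
        assert summary.mean is None and summary.min is None and summary.max is None


class TestJitter:
    def _parts(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        return make_participants([f"S{i}" for i in range(n)],
                                 rng.uniform(12, 14, n), rng.uniform(50, 54, n))

    def test_zero_offset_identity(self):
        parts = self._parts()
        out = jitter_coordinates(parts, 0.0, seed=1)
        assert np.array_equal(out.lons, parts.lons)
        assert np.array_equal(out.lats, parts.lats)

    def test_same_seed_same_output(self):
        parts = self._parts()
        a = jitter_coordinates(parts, 100.0, seed=9)
        b = jitter_coordinates(parts, 100.0, seed=9)
        assert np.array_equal(a.lons, b.lons) and np.array_equal(a.lats, b.lats)

    def test_displacements_bounded_planar(self):
        parts = self._parts(n=1000, seed=4)
        out = jitter_coordinates(parts, 100.0, seed=2)
        dy = (out.lats - parts.lats) * METERS_PER_DEGREE
        dx = (out.lons - parts.lons) * METERS_PER_DEGREE * np.cos(np.radians(parts.lats))
        assert (np.hypot(dx, dy) <= 100.0 + 1e-6).all()

    def test_offsets_stable_under_row_reordering(self):
        parts = self._parts(n=50)
        out = jitter_coordinates(parts, 100.0, seed=5)
        order = np.arange(50)[::-1]
        shuffled = make_participants([parts.subject_ids[i] for i in order],
                                     parts.lons[order], parts.lats[order])
        out_shuffled = jitter_coordinates(shuffled, 100.0, seed=5)
        lookup = dict(zip(out_shuffled.subject_ids, out_shuffled.lons))
        assert all(lookup[sid] == lon for sid, lon in zip(out.subject_ids, out.lons))


class TestSnapToGrid:
    def test_same_cell_same_snap(self):
        parts = make_participants(["a", "b"], [13.001, 13.009], [52.001, 52.009])
        out = snap_to_grid(parts, 0.01)
        assert out.lons[0] == out.lons[1] and out.lats[0] == out.lats[1]

    def test_cell_center_unchanged(self):
        parts = make_participants(["a"], [13.005], [52.015])
        out = snap_to_grid(parts, 0.01)
        assert out.lons[0] == pytest.approx(13.005)
        assert out.lats[0] == pytest.approx(52.015)

    @settings(derandomize=True, max_examples=50)
    @given(lon=st.floats(-179, 179), lat=st.floats(-89, 89),
           cell=st.floats(0.001, 5.0))
    def test_snapped_point_stays_in_its_cell(self, lon, lat, cell):
        """Snapping maps a point to the center of the cell containing it."""
        parts = make_participants(["a"], [lon], [lat])
        out = snap_to_grid(parts, cell)
        assert abs(out.lons[0] - lon) <= cell / 2 + 1e-9 * cell
        assert abs(out.lats[0] - lat) <= cell / 2 + 1e-9 * cell

    def test_displacement_bounded_by_half_cell(self):
        rng = np.random.default_rng(12)
        parts = make_participants([f"S{i}" for i in range(500)],
                                  rng.uniform(-170, 170, 500),
                                  rng.uniform(-80, 80, 500))
        out = snap_to_grid(parts, 0.25)
        assert (np.abs(out.lons - parts.lons) <= 0.125 + 1e-12).all()
        assert (np.abs(out.lats - parts.lats) <= 0.125 + 1e-12).all()
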