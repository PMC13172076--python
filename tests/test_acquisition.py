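"""Provider adapters, bbox subsetting, tile stitching and job materialization."""

import numpy as np
import pytest

from envlink import (
    BoundingBox,
    FixtureField,
    FixtureProvider,
    FlakyProvider,
    GridTransform,
    ProviderRequest,
    RasterGrid,
    StubNetworkProvider,
    materialize,
    make_raster_fixture,
    populate_fixture_provider,
    stitch_tiles,
    subset_to_bbox,
)
from envlink.acquisition import CredentialRef
from envlink.config import Job
from envlink.errors import EmptyExtentError, FetchError, StitchError
from envlink.store import file_checksum, is_complete

from conftest import BERLIN_BOX, small_grid, source_doc


def box(n, w, s, e):
    return BoundingBox(north=n, west=w, south=s, east=e)


@pytest.fixture
def fixture_root(tmp_path, dem_source):
    field = FixtureField(kind="plane", a=10.0, b=-3.0, c=1.0, extent=BERLIN_BOX,
                         resolution=0.01)
    populate_fixture_provider(tmp_path / "fix", [dem_source], [], {
        ("dem", "elevation"): field,
    })
    return tmp_path / "fix"


class TestFixtureProvider:
    def test_existing_layer_returned_unchanged(self, fixture_root):
        provider = FixtureProvider(fixture_root)
        field = FixtureField(kind="plane", a=10.0, b=-3.0, c=1.0, extent=BERLIN_BOX,
                             resolution=0.01)
        [layer] = provider.fetch(ProviderRequest("dem", "elevation", "static", BERLIN_BOX))
        assert layer.equals(make_raster_fixture(field))

    def test_missing_year_raises_fetch_error(self, fixture_root):
        provider = FixtureProvider(fixture_root)
        with pytest.raises(FetchError):
            provider.fetch(ProviderRequest("dem", "elevation", "1999", BERLIN_BOX))

    def test_flaky_provider_fails_then_succeeds(self, fixture_root):
        key = ("dem", "elevation", "static")
        provider = FlakyProvider(FixtureProvider(fixture_root), {key: 1})
        request = ProviderRequest(*key, BERLIN_BOX)
        with pytest.raises(FetchError):
            provider.fetch(request)
        assert provider.fetch(request)  # second attempt succeeds

    def test_stub_network_provider_never_fetches(self):
        provider = StubNetworkProvider("era5", "https://example.invalid")
        with pytest.raises(FetchError, match="not configured"):
            provider.fetch(ProviderRequest("era5", "t2m", "2023", BERLIN_BOX))

    def test_credential_file_contract(self, tmp_path):
        cred = CredentialRef("cds_climate", "cdsapirc_climate.sct")
        with pytest.raises(FetchError, match="cdsapirc_climate.sct"):
            cred.resolve(tmp_path)
        (tmp_path / "cdsapirc_climate.sct").write_text("key: abc\n")
        assert cred.resolve(tmp_path).name == "cdsapirc_climate.sct"


class TestSubsetToBbox:
    def test_full_extent_is_identity(self):
        grid = small_grid(np.arange(16.0).reshape(4, 4), crs="EPSG:4326")
        sub = subset_to_bbox(grid, box(4, 0, 0, 4))
        assert sub.equals(grid)

    def test_west_half_of_unit_grid(self):
        # centers 0.5..3.5; box [0, 2] keeps centers 0.5 and 1.5 -> 2 columns
        grid = small_grid(np.arange(16.0).reshape(4, 4), crs="EPSG:4326")
        sub = subset_to_bbox(grid, box(4, 0, 0, 2))
        assert sub.shape == (4, 2)
        assert sub.transform.x_origin == grid.transform.x_origin
        assert np.array_equal(sub.values, grid.values[:, :2])

    def test_disjoint_box_raises(self):
        grid = small_grid(np.ones((4, 4)), crs="EPSG:4326")
        with pytest.raises(EmptyExtentError):
            subset_to_bbox(grid, box(50, 40, 41, 49))

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        grid = small_grid(rng.normal(size=(9, 7)), crs="EPSG:4326")
        b = box(6.3, 1.2, 2.1, 5.9)
        once = subset_to_bbox(grid, b)
        twice = subset_to_bbox(once, b)
        assert twice.equals(once)


def split_tiles(grid, n_cols_splits=2, n_rows_splits=1):
    """Partition a grid into aligned tiles (test helper)."""
    rows, cols = grid.shape
    t = grid.transform
    tiles = []
    r_edges = np.linspace(0, rows, n_rows_splits + 1).astype(int)
    c_edges = np.linspace(0, cols, n_cols_splits + 1).astype(int)
    for r0, r1 in zip(r_edges[:-1], r_edges[1:]):
        for c0, c1 in zip(c_edges[:-1], c_edges[1:]):
            tiles.append(RasterGrid(
                grid.values[r0:r1, c0:c1].copy(),
                GridTransform(t.x_origin + c0 * t.x_size, t.y_origin - r0 * t.y_size,
                              t.x_size, t.y_size),
                grid.crs_id, grid.nodata))
    return tiles


class TestStitchTiles:
    def test_single_tile_identity(self):
        grid = small_grid(np.ones((3, 3)))
        assert stitch_tiles([grid]).equals(grid)

    def test_two_abutting_tiles_east_west(self):
        left = small_grid([[1.0, 2.0], [3.0, 4.0]], x0=0.0, y0=2.0)
        right = small_grid([[5.0, 6.0], [7.0, 8.0]], x0=2.0, y0=2.0)
        mosaic = stitch_tiles([left, right])
        assert mosaic.shape == (2, 4)
        # every input value sits at its original georeferenced position
        from envlink import sample_raster
        assert sample_raster(mosaic, [(0.5, 1.5), (1.5, 0.5), (2.5, 1.5), (3.5, 0.5)]) \
            == [1.0, 4.0, 5.0, 8.0]

    def test_partition_reconstructs_original(self):
        rng = np.random.default_rng(8)
        grid = small_grid(rng.normal(size=(12, 10)))
        for splits in [(2, 1), (2, 2), (5, 3)]:
            mosaic = stitch_tiles(split_tiles(grid, *splits))
            assert mosaic.equals(grid)

    def test_identical_overlap_is_consistent(self):
        grid = small_grid(np.arange(12.0).reshape(3, 4))
        a = RasterGrid(grid.values[:, :3].copy(), grid.transform, grid.crs_id, grid.nodata)
        t = grid.transform
        b = RasterGrid(grid.values[:, 1:].copy(),
                       GridTransform(t.x_origin + t.x_size, t.y_origin, t.x_size, t.y_size),
                       grid.crs_id, grid.nodata)
        mosaic = stitch_tiles([a, b])
        assert mosaic.equals(grid)

    def test_conflicting_overlap_raises_in_strict_mode(self):
        a = small_grid(np.ones((2, 2)))
        conflicting = small_grid(np.zeros((2, 2)))
        with pytest.raises(StitchError, match="conflict"):
            stitch_tiles([a, conflicting])

    def test_first_wins_override(self):
        a = small_grid(np.ones((2, 2)))
        b = small_grid(np.zeros((2, 2)))
        mosaic = stitch_tiles([a, b], first_wins=True)
        assert np.array_equal(mosaic.values, a.values)

    def test_uncovered_cells_are_nodata(self):
        a = small_grid(np.ones((1, 1)), x0=0.0, y0=1.0)
        b = small_grid(np.full((1, 1), 2.0), x0=2.0, y0=3.0)
        mosaic = stitch_tiles([a, b])
        assert mosaic.shape == (3, 3)
        assert (mosaic.values == -9999.0).sum() == 7

    @pytest.mark.parametrize("mutate", [
        lambda t: RasterGrid(t.values, t.transform, "EPSG:9999", t.nodata),
        lambda t: RasterGrid(t.values, GridTransform(0.5, 2.0, 1.0, 1.0),
                             t.crs_id, t.nodata),  # misaligned origin
        lambda t: RasterGrid(t.values, GridTransform(0.0, 2.0, 2.0, 1.0),
                             t.crs_id, t.nodata),  # resolution mismatch
    ])
    def test_incompatible_tiles_rejected(self, mutate):
        a = small_grid(np.ones((2, 2)))
        with pytest.raises(StitchError):
            stitch_tiles([a, mutate(small_grid(np.ones((2, 2)), x0=2.0))])


class TestMaterialize:
    def _job(self, store, fmt="geotiff"):
        from envlink.store import dataset_path
        return Job("dem", "elevation", "static",
                   dataset_path("", "dem", "elevation", "static", fmt))

    def test_pending_job_completes_and_rerun_is_noop(self, tmp_path, fixture_root):
        store = tmp_path / "db"
        job = self._job(store)
        provider = FixtureProvider(fixture_root)
        path = materialize(job, provider, store, BERLIN_BOX)
        assert is_complete(path)
        checksum = file_checksum(path)
        materialize(job, provider, store, BERLIN_BOX)  # idempotent
        assert file_checksum(path) == checksum

    def test_fetch_error_leaves_no_sentinel(self, tmp_path, fixture_root):
        store = tmp_path / "db"
        job = self._job(store)
        provider = FlakyProvider(FixtureProvider(fixture_root),
                                 {("dem", "elevation", "static"): 1})
        with pytest.raises(FetchError):
            materialize(job, provider, store, BERLIN_BOX)
        assert not is_complete(store / job.target)
        # retry completes the job (resume)
        materialize(job, provider, store, BERLIN_BOX)
        assert is_complete(store / job.target)

    def test_tiled_fixture_matches_untiled(self, tmp_path, dem_source):
        field = FixtureField(kind="plane", a=10.0, b=-3.0, c=1.0, extent=BERLIN_BOX,
                             resolution=0.01)
        fields = {("dem", "elevation"): field}
        populate_fixture_provider(tmp_path / "untiled", [dem_source], [], fields)
        populate_fixture_provider(tmp_path / "tiled", [dem_source], [], fields, tiled=4)
        job = self._job(None)
        p1 = materialize(job, FixtureProvider(tmp_path / "untiled"),
                         tmp_path / "db1", BERLIN_BOX)
        p2 = materialize(job, FixtureProvider(tmp_path / "tiled"),
                         tmp_path / "db2", BERLIN_BOX)
        assert file_checksum(p1) == file_checksum(p2)
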