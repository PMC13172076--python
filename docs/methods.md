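# Methods

## Scope and data model

`envlink` builds a local, file-based database of environmental layers and
links participant coordinates to it. Three containers carry all gridded
data: `RasterGrid` (single-band 2-D values + affine geotransform + CRS id
+ nodata sentinel), `GridCube` (a (time, y, x) stack with strictly
increasing timestamps), and plain `DataFrame`s for regional indicator
tables. The geotransform convention is fixed package-wide: the origin is
the outer corner of the top-left pixel, pixel sizes are positive, the row
index increases southward, and cells are half-open
`[x, x+dx) × (y−dy, y]`. Every piece of sampling, subsetting and
stitching arithmetic derives from this one convention, which is why
point-on-boundary behaviour is deterministic and bit-reproducible.

Layers are stored one file per (source, variable, year) at
`root/<source>/<variable>/<source>_<variable>_<year>.<ext>` — `tif` for
single-band rasters, `nc` for cubes, `csv` for tables; non-temporal
layers use the literal year tag `static`. Identifiers are restricted to
`[A-Za-z0-9_-]` so paths cannot escape the store.

## Configuration and job planning

A workflow config (folders, requested years, named area) plus one spec
per source (access kind, storage format, native CRS, coverage box,
available years, variables with optional neighbourhood metrics) plus a
bounding-box registry produce a flat job plan. Planning rules:

- Years are the intersection of requested and available years; in update
  mode `update_years` alone defines the request (it is deliberately not
  required to be a subset of `years` — updating can extend a database).
- A source whose coverage box does not intersect the resolved area is
  dropped with a warning; boxes sharing only an edge count as disjoint,
  since a zero-area overlap contains no pixel centers.
- Static sources contribute exactly one `static` job.
- The plan is deterministically ordered (source order, variable order,
  ascending years), so two plans from identical inputs are identical.

Registry entries are `[north, west, south, east]` arrays. Registry JSON
may use U+2212 minus signs (as published listings sometimes do); the
parser normalizes them. Antimeridian-crossing boxes are rejected. Unknown
workflow-config keys warn rather than fail, for forward compatibility.

## Storage formats

GeoTIFF I/O is a thin layer over `tifffile`: georeferencing is written as
the standard ModelPixelScale/ModelTiepoint tags, a minimal
GeoKeyDirectory (EPSG code when the CRS id carries one, user-defined
otherwise), a GDAL-style ASCII nodata tag, and a JSON ImageDescription
holding the exact CRS id and nodata value. Reading prefers the JSON
block and falls back to the tags, so files written here round-trip
values, transform, CRS and nodata exactly (bit-exact for integer grids,
IEEE-exact for floats). Cubes are CF-style NETCDF3 files written through
xarray's scipy backend — one named data variable per file on
(time, y, x), time encoded as float64 seconds since 1970 (exact for any
realistic epoch), and the geotransform recorded in global attributes so
single-row/column grids round-trip unambiguously. Indicator CSVs are
stored verbatim; no geometry is attached.

## Completeness and resume

A data file is complete iff `<file>.ok` exists and contains the file's
SHA-256. The sentinel is written strictly after the data file, so any
interruption leaves either no file or a sentinel-less file, both
classified incomplete by `scan_store`. The builder marks planned jobs
complete from the manifest, attempts the rest, and recomputes any
requested metric layer whose own sentinel is missing — so a crash at any
point (including between a layer and its derived metrics) is repaired by
rerunning. Because fixtures are deterministic and outputs embed no
timestamps, a killed-and-resumed store is checksum-identical to an
uninterrupted one; the acceptance script verifies this for kill points
k = 1..5.

## Acquisition and assembly

Providers implement a single `fetch(request) -> [layers]` contract.
Network adapters (climate/atmosphere stores, web map services, direct
downloads) are stubs that keep the credential-file interface
(`cdsapirc_climate.sct`, `cdsapirc_atmo.sct`, `nasa.sct` under the
configured secrets folder) but raise a retryable fetch error; the
filesystem `FixtureProvider` serves pre-generated files and is the test
and offline path. Fetch errors mark the job incomplete and, with
keep-going semantics, do not abort the remaining jobs.

Subsetting keeps exactly the pixels whose centers fall inside the
requested box (closed interval on the box edges); this is idempotent and
unambiguous under the half-open cell model. Stitching requires shared
CRS, equal pixel sizes and integer-pixel origin offsets; the mosaic
covers the union extent, uncovered cells are nodata, and overlapping
valid cells must agree exactly (strict mode) unless a first-wins
override is chosen — providers' tile overlaps are expected to agree, so
disagreement is treated as data corruption rather than silently
resolved.

## Neighbourhood metrics

Focal mean/SD/variance use a circular kernel: offsets with Euclidean
norm ≤ r pixels, fractional radii allowed so metric radii (e.g. 500 m)
need not land on integer pixels. Radius conversion divides by the pixel
size on projected (meter) grids and by 111320 m/degree times the
north–south pixel size on geographic grids; east–west anisotropy of
geographic cells is ignored in this version. The implementation
accumulates shifted copies of the valid-masked grid in sorted offset
order; because a naive per-cell loop over the same sorted offsets
performs the identical IEEE additions, the two agree to the bit, and the
test suite asserts exact (not approximate) equality against such an
oracle on seeded grids with random nodata. Variance uses the population
(n) divisor — these are texture filters, not inferential estimates — and
E[z²] − E[z]² with a clamp at zero for rounding. Edge policy is the
shrinking window: statistics over whatever valid cells remain, nodata
only when none do.

Slope/aspect use second-order central differences on the four rook
neighbours (exact on planes, the property the acceptance tests check to
1e−9 degrees). Slope is reported in degrees; aspect as the compass
bearing of the downslope vector, 0° = north, clockwise, with flat cells
(p = q = 0) mapped to nodata; border cells and cells with any nodata
rook neighbour are nodata in both outputs. For geographic DEMs the cell
size derives from the north–south pixel size at 111320 m/degree.

## Linkage

Participant tables require subject id, WGS84 longitude and latitude
(headers matched case-insensitively; common aliases accepted); range
violations and duplicate ids are rejected with row numbers. Coordinates
are transformed into each layer's native CRS — identity for geographic
layers, the analytic sinusoidal forward map for MODIS-style layers
(default sphere radius 6 371 007.181 m, configurable via a CRS id of the
form `SINUSOIDAL:R=<meters>`), and a user-registered engine for anything
else; with no engine registered, unsupported CRSs raise rather than
guess. Raster linkage writes one CSV per complete layer with a
`<source>__<variable>__<year>` column, preserving input row order and
writing empty fields for unsampled subjects. Cube linkage groups
subjects by pixel and stores each occupied pixel's series once; the JSON
schema has fixed keys (variable, crs, time, groups, unmatched). Routes
are sampled per point and summarised by mean/min/max over valid samples
(length-weighted averaging would be a natural extension and is not
implemented).

Jitter displaces each point uniformly within a disk of the given radius,
using offsets derived from SHA-256 of (seed, subject id) — stable under
row reordering, reproducible across platforms, and bounded by
construction (meters converted to degrees at each point's latitude).
Snapping replaces coordinates by their cell centers on a grid anchored
at 0°, displacement at most half a cell per axis.

## Synthetic data

The fixture generators emulate the *structure* of provider data, not its
physics: constant, plane, Gaussian-bump, seeded-noise and checkerboard
fields over a configurable geographic window (default ≈ 0.8° × 0.4°,
Berlin-sized, at 0.01° resolution so degree/meter conversions are
exercised on small arrays), multi-year cubes with per-step fields keyed
by (seed, step), and uniform participant tables with a fixed fraction
placed just outside the box for reproducible unmatched counts. Plane
fields make the terrain derivatives and symmetric-kernel focal means
analytically checkable; constant cubes force all linked series equal.
Passing tests on these fixtures demonstrates the correctness of the
pipeline's arithmetic and bookkeeping — they say nothing about provider
data quality, real-world CRS metadata quirks, or network behaviour,
which are exactly the parts stubbed out behind the provider contract.

## Problem sizes and numerical choices

The test and acceptance workloads are deliberately small: 64×64 oracle
grids (20 seeds × 4 radii), 33×33 planes, 20×20 cubes with up to 1000
subjects, 7-job pipelines for resume replay, and a 10,000-subject ×
(2 rasters + 24-step cube) linkage for the throughput check — sizes
chosen so the full suite runs in well under a minute on one CPU while
still exercising every code path at realistic aspect ratios. Floating
comparisons in tests are exact where the algorithm guarantees it
(focal oracle, round-trips) and 1e−9-degree bounds where only analytic
exactness up to IEEE rounding is guaranteed (plane derivatives,
projection inverses).

## Known limitations

Single-band rasters only; no reprojection between layer CRSs (layers
stay native, by design); geographic kernels are isotropic in pixel
space, so east–west metric radii stretch away from the equator; no
adaptive-bandwidth kernels, curvature, or higher-order terrain
derivatives; no real network clients, authentication, or retry policy;
cube linkage returns full series without temporal matching to
participant timestamps; route summaries are unweighted.
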