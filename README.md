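# envlink

Toolkit for building a harmonized, file-based database of local
environmental exposures and linking participant coordinates to it.

Epidemiological and exposomics studies increasingly need individual-level
environmental context — elevation and terrain, settlement density, land
cover, air pollutants, reanalysis climate series — attached to cohort
participants' locations. Assembling that context is mostly plumbing:
heterogeneous providers, formats (GeoTIFF, netCDF, CSV), native map
projections, partial temporal and regional availability, and multi-day
downloads that fail halfway through. `envlink` packages that plumbing as
a config-driven, incremental, resumable pipeline that runs entirely on
the local filesystem — participant coordinates never leave the machine,
which matters wherever geolocation data is governed by data-protection
rules. Provider access is behind an adapter contract; a filesystem
fixture provider (plus seeded synthetic generators) gives the whole
pipeline a test surface with no network access.

## What it computes

**Neighbourhood (focal) statistics.** For a raster value surface z and a
circular kernel K_r = {(dr, dc) : sqrt(dr² + dc²) ≤ r}, the focal mean,
population variance and standard deviation at cell (i, j) are taken over
the valid (in-bounds, non-nodata) cells of K_r centered there:

    mean = (1/n) Σ z_k,   var = (1/n) Σ z_k² − mean²,   sd = √var

Windows shrink at borders and around nodata; a cell with no valid
neighbour becomes nodata. Small radii capture local texture, large radii
broader context.

**Terrain derivatives.** Slope and aspect come from second-order central
differences on a DEM's four rook neighbours (the Zevenbergen–Thorne
scheme): with cell size g,

    p = (z_E − z_W) / 2g,  q = (z_N − z_S) / 2g
    slope  = arctan √(p² + q²)            (degrees)
    aspect = atan2(−p, −q) mod 360        (degrees clockwise from north,
                                           downslope direction)

The scheme is exact on planes, which the test suite exploits.

**Coordinate transformation and sampling.** Participant coordinates
(WGS84 lon/lat) are transformed into each layer's native CRS before
sampling — rasters are never resampled. The spherical sinusoidal
equal-area projection used by MODIS vegetation products is built in:

    x = R λ cos φ,  y = R φ     (λ, φ in radians; R = 6 371 007.181 m)

with its exact analytic inverse. Sampling uses half-open pixel cells:
col = ⌊(x − x₀)/dx⌋, row = ⌊(y₀ − y)/dy⌋, so ties on boundaries are
deterministic.

**Pixel-grouped time-series linkage.** For netCDF cubes, subjects falling
in the same pixel are grouped and the pixel's full series is stored once
per group — the stored-series count equals the number of distinct
occupied pixels, never the number of subjects.

**Incremental build with resume.** Jobs are planned as
(source, variable, year) tasks filtered by year and regional
availability; each materialized file gets a `.ok` sentinel holding its
SHA-256, written only after the data file. Interrupted runs resume from
the sentinel manifest and reproduce the uninterrupted store
checksum-for-checksum.

**Privacy utilities.** Uniform-disk jittering (per-subject deterministic,
keyed by seed and subject id) and snapping to grid-cell centers, for use
before linkage where governance requires coordinate coarsening.

## Worked example

`examples/terrain_and_neighbourhood_metrics.py` builds a 60×60 plane DEM
z = 0.4x + 0.3y on a 1 m grid and prints:

```
circular kernel r=3 covers 29 cells
focal mean at grid center: 21.050000 (plane value there: 21.050000)
slope at interior cells : 26.565051 deg (analytic 26.565051)
aspect at interior cells: 233.130102 deg (analytic 233.130102)
focal SD on the plane is constant texture: 0.765641
```

The focal mean of a plane equals the plane under a symmetric kernel; the
slope is arctan(0.5) = 26.565° everywhere, and the aspect is the compass
bearing of the downslope vector (−0.4, −0.3), i.e. 233.13°. The other
examples cover database building with resume (`build_database.py`),
point and cube linkage (`link_participants.py`), and coordinate
obfuscation (`privacy_jitter_snap.py`); each prints a short explanation
with its numbers.

A thin CLI mirrors the library for shell use:
`envlink build --config config.json`, `envlink link locations.csv
store_dir out_dir`, plus `areas`, `catalog`, `validate`.

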