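"""Link participant coordinates to raster layers and a time-series cube.

Writes a tiny store (an elevation plane and a 12-step temperature cube),
generates 8 participants (one deliberately outside the area), and runs the
linkage. Raster layers yield one CSV column per layer; the cube yields a
compact JSON where subjects sharing a pixel are grouped and each occupied
pixel's series is stored once.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

from envlink import (
    BoundingBox,
    FixtureField,
    make_cube_fixture,
    make_participants_fixture,
    make_raster_fixture,
    run_link,
)
from envlink.fixtures import write_complete_layer

berlin = BoundingBox(north=52.7136, west=12.9673, south=52.2839, east=13.816)

with TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    dem = make_raster_fixture(FixtureField(kind="plane", a=100.0, b=50.0, c=0.0,
                                           extent=berlin, resolution=0.01))
    cube = make_cube_fixture(FixtureField(kind="seeded_noise", seed=4, c=283.0,
                                          amplitude=5.0, extent=berlin,
                                          resolution=0.1), [2023])
    cube.variable = "t2m"
    write_complete_layer(tmp / "db", "dem", "elevation", "static", dem)
    write_complete_layer(tmp / "db", "era5", "t2m", "2023", cube)

    participants = make_participants_fixture(8, berlin, seed=5,
                                             out_of_bounds_fraction=0.125)
    report = run_link(None, tmp / "db", tmp / "out", participants=participants)
    print(f"linked layers: {report.jobs_completed}")

    csv = (tmp / "out" / "dem_elevation_static.csv").read_text().splitlines()
    print("raster CSV (subject_id, sampled elevation):")
    for line in csv[:4]:
        print(f"  {line}")

    doc = json.loads((tmp / "out" / "era5_t2m_2023.json").read_text())
    print(f"cube JSON: {len(doc['groups'])} pixel groups for 8 subjects, "
          f"{len(doc['unmatched'])} unmatched, {len(doc['time'])} timesteps")
    g = doc["groups"][0]
    print(f"  first group: pixel {g['pixel']}, subjects {g['subjects']}, "
          f"series[0] = {g['series'][0]:.3f} K")

# Subjects in the same 0.1 degree cube pixel share one stored series.
# Subjects whose point falls outside a layer's pixel grid (the one placed
# beyond the Berlin box, plus any in the margin the coarse 0.1 degree grid
# does not cover) are reported as unmatched or an empty CSV field — never
# silently dropped.
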