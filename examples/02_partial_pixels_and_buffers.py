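"""Partial-pixel apportionment and UTM buffering.

Shows the core apportionment rule — a half-covered 100-person cell
contributes 50 people — and that buffering a point by d meters in its
best-fit UTM zone produces a disk of area ~ pi d^2.
"""

import math, os, tempfile

from shapely.geometry import Point, box

from nearpop import (
    CRS,
    FixtureSpec,
    buffer_one,
    cell_coverage,
    make_raster,
    utm_for,
    weighted_sum,
)
from nearpop.crs import transform_geom

# 1. apportionment: one 100-person cell, hazard covering its left half
spec = FixtureSpec(grid_shape=(1, 1), cell_size=100.0, fill=("uniform", 100.0))
with make_raster(spec, os.path.join(tempfile.mkdtemp(), "pixel.tif")) as raster:
    t = spec.transform
    half = box(t.x0, t.y0 + t.dy, t.x0 + t.dx / 2, t.y0)
    cov = cell_coverage(half, raster)
    print(f"covered fraction of the cell: {cov.fracs[0]:.3f}")
    print(f"people contributed: {weighted_sum(raster, cov):.1f}  (100 people x 0.5)")

# 2. metric buffering in the best-fit UTM zone
lon, lat, d = -118.7, 34.0, 10_000.0
zone = utm_for(lon, lat)
disk = buffer_one(Point(lon, lat), CRS(4326), d)
area = transform_geom(disk, CRS(4326), zone.crs).area
print(f"\npoint ({lon}, {lat}) falls in UTM zone {zone.zone} (EPSG:{zone.code})")
print(f"10 km buffer area: {area/1e6:.2f} km^2 vs circle {math.pi*d*d/1e6:.2f} km^2")
print("(the small gap is the polygonal approximation of the circular arc)")
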