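# nearpop

**nearpop** estimates the number of people residing near environmental
hazards. Given hazard geometries (wildfire burn zones, well pads, storm
tracks, industrial sites — points, lines, or polygons), per-hazard buffer
distances in meters, and a gridded population raster, it buffers each
hazard in its best-fit UTM projection, overlays the buffered areas on the
raster with exact partial-pixel apportionment, and reports exposed-population
counts — per hazard or for the union of all hazards — optionally decomposed
by administrative units (ZCTAs, tracts, counties) with matching
raster-derived denominators. It is written for environmental
epidemiologists and exposure scientists who need these counts to be
reproducible and consistent across studies.

## The method

For hazard *i* with buffer distance *d<sub>i</sub>* (meters), the exposed
geometry is the dilation *B(g<sub>i</sub>, d<sub>i</sub>)* computed in the
UTM zone of the hazard's centroid, so distances are metric with minimal
distortion. For a population raster with cell values *p<sub>k</sub>*
(persons per cell), the exposed population is the coverage-weighted sum

> E<sub>i</sub> = Σ<sub>k</sub> w<sub>ik</sub> · p<sub>k</sub>,  w<sub>ik</sub> = area(B<sub>i</sub> ∩ cell<sub>k</sub>) / area(cell<sub>k</sub>) ∈ [0, 1]

so a cell of 100 people half-covered by a buffered hazard contributes
exactly 50 — the uniform-within-cell assumption standard for gridded
population products. Cumulative counts replace *B<sub>i</sub>* with the
union ∪<sub>i</sub> B<sub>i</sub>, counting each person once no matter how
many hazards they live near; admin-unit decompositions intersect the
(unioned) buffers with each unit polygon. Coverage weights come from exact
axis-aligned clipping of the polygon against cell rectangles, not from
centroid or all-touched masking, and extraction reads only the raster
window under each geometry (or each connected component of overlapping
geometries), so memory scales with the hazard footprint rather than the
raster.

## Worked example

`examples/01_exposed_population.py` builds a 20×20 raster of one person
per 100 m cell and two 10×10-cell hazards overlapping in 50 cells:

```
hazard-specific counts (people near each hazard; overlaps double-counted):
ID_hazard  exposed_main
    haz_0         100.0
    haz_1         100.0

cumulative count (union of hazards; each person counted once):
 exposed_main
        150.0
```

Each hazard covers 100 one-person cells, so each hazard-specific count is
100; the union covers 150 cells, so the cumulative count is 150 — the 50
people near both hazards are counted once instead of twice. The other
examples show the half-pixel apportionment rule and UTM buffering
(`02_partial_pixels_and_buffers.py`) and per-admin-unit proportions with
consistent denominators (`03_admin_units_and_denominators.py`).

The same pipeline is available from the shell:

```sh
nearpop buffer  --hazards hazards.parquet --out buffered.parquet
nearpop exposed --hazards buffered.parquet --pop pop.tif --cumulative --out exposed.csv
nearpop total   --admin zctas.parquet --pop pop.tif --out denominators.csv
```

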