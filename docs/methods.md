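# Methods

## Model and assumptions

nearpop estimates residential proximity exposure: a person is exposed to a
hazard if their residence lies within a stated distance of it. The
procedure is buffer → overlay → sum:

1. **Buffering.** Each hazard geometry is reprojected to the UTM zone of
   its centroid (the standard 6° bands; hemisphere from the centroid
   latitude), dilated by its buffer distance in meters, and reprojected
   back to a common lon/lat CRS. Using a per-feature zone keeps metric
   distortion small even for hazard sets spanning a continent; a set
   covering CONUS longitudes uses ten different zones (10–19).
2. **Overlay.** Buffered geometries (or their union, or their
   intersections with administrative units) are reprojected to the
   raster's CRS — the raster itself is never resampled, since resampling
   redistributes people and breaks count conservation.
3. **Sum.** Each raster cell contributes `value × fraction`, where the
   fraction is the exact share of the cell's area covered by the polygon.
   This assumes population is uniform within a cell, the usual assumption
   for gridded population products; it avoids the biases of centroid
   masking (cells counted all-or-nothing) and all-touched masking (every
   touched cell counted in full).

Counts are reported as real numbers. Partial-pixel weighting is inherently
fractional; rounding is the caller's choice.

## Exposure modes

`est_exposed_pop` supports the cross of two choices. *Hazard-specific*
counts are computed per hazard, so people near several hazards appear in
each hazard's count; *cumulative* counts merge each buffered-hazard column
into a single union first, counting each person once. With administrative
units, counts are taken over the intersection of the (unioned) buffer with
each unit. Multiple buffer definitions travel as parallel columns
(`buffer_dist_<suffix>` → `buffered_hazard_<suffix>` → `exposed_<suffix>`)
and never mix: unions and intersections are computed per column.
`est_total_pop` computes each unit's resident population from the same
raster with the same apportionment, so proportions exposed have consistent
numerators and denominators.

In hazard-specific × admin mode, rows are emitted for hazard–unit pairs
whose bounding boxes intersect (non-candidate pairs are exact zeros);
`all_pairs=True` / `--all-pairs` forces the full cross product with
explicit zero rows.

## Coordinate systems and projection accuracy

Supported CRSs are WGS84 lon/lat (EPSG:4326) and the WGS84 UTM zones
(EPSG:32601–32660, 32701–32760) — the systems the method itself uses and
in which common population grids are published. Other EPSG codes raise an
error rather than being silently assumed; a vector file with no CRS
declaration is likewise an error. Conversion uses the Krüger series form
of the transverse Mercator projection carried to fourth order in the third
flattening; within a zone it agrees with an independently coded
Redfearn/Snyder-series oracle to under a centimeter and round-trips to
1e-8 degrees. Latitudes poleward of ±84° keep the formula-derived zone (no
polar special case) and geometries crossing the antimeridian are
unsupported; both are limitations, not silent behaviors.

## Numerical choices

- **Coverage fractions** come from exact axis-aligned clipping
  (polygon ∩ cell rectangle, shapely's exact constructive geometry). Cells
  strictly inside the polygon get fraction 1 without clipping. Fractions
  are clamped to [0, 1]; a clamp beyond 1e-9 raises an internal
  consistency error instead of being absorbed.
- **Windowing.** Extraction scans only the cells in the polygon's
  bounding box, padded by one cell and aligned to whole cell boundaries so
  partially covered edge cells are included; the box is processed in
  512-row blocks to bound the number of live cell rectangles. Raster reads
  decode only the TIFF tiles/strips the window touches.
- **Nodata** cells contribute zero people but still count toward covered
  area (nodata means "no population recorded", not "no land"). Negative
  population values are rejected. Polygon holes subtract from coverage.
- **Buffer discretization** uses 32 segments per quarter circle, keeping a
  point-buffer's area within 0.1% of the true circle (tests allow 0.5%).
  A zero-distance buffer returns polygons unchanged; points and lines
  dilate to an empty polygon at distance zero.
- **Grouping.** For cumulative counts, buffered geometries are grouped
  into connected components of the pairwise-intersects relation (bounding
  boxes only prefilter candidates); each component is unioned and
  extracted with its own raster window, so disjoint clusters never force
  one large read.
- **Cleaning.** Invalid geometries are repaired with shapely's
  structure-preserving make-valid; rows whose geometry is missing, empty,
  or unrepairable are dropped with their IDs, and a table with no
  survivors becomes `None`. Cleaning is idempotent and applied to hazards
  and admin units alike before estimation.

## Synthetic data

The fixture generators produce GeoTIFF rasters (uniform, seeded-random, or
row-ramp fills), grid-aligned rectangular hazards, and exact rectangular
admin tilings. Defaults emulate the resolution class of real gridded
population products: 100 m cells in a metric UTM CRS (EPSG:32611),
anchored at the zone's central meridian so grid-aligned shapes have exact
closed-form answers; a lon/lat variant exercises the reprojection and UTM
buffering paths. Everything is deterministic given its arguments and seed.

What the fixtures do *not* emulate: realistic settlement patterns (spatial
autocorrelation, zeros over water, heavy-tailed urban densities),
irregular admin boundaries, or very large rasters. Passing tests therefore
demonstrate the correctness of the geometry and apportionment machinery —
which is scale- and pattern-independent — but not performance at
continental scale or robustness to malformed real-world files beyond the
cleaning rules above. Test problem sizes (20×20 to 40×40 grids, tens of
polygons) were chosen so the closed-form answers are exact and the whole
suite runs in seconds.

## Interfaces

Vectors are GeoJSON (RFC 7946) or GeoParquet; GeoJSON written by the
package is always lon/lat per the standard (tables are reprojected on
write), while GeoParquet preserves any supported CRS. GeoJSON cannot carry
several geometry columns, so secondary `buffered_hazard_*` columns are
encoded as WKT properties and decoded on read; GeoParquet stores them
natively as WKB. Rasters are single-band GeoTIFFs; band 1 is the
population band and nodata is read from file metadata. Results are CSV or
Parquet with the exact column names `ID_hazard`, `ID_admin_unit`,
`exposed_<suffix>`, `population`. The CLI (`nearpop buffer | exposed |
total`) exits 0 on success, 2 on schema errors, 3 on I/O errors, 4 on CRS
errors.

## Known limitations

- Only EPSG:4326 and WGS84 UTM CRSs; no shapefile input; no raster
  reprojection or resampling; single-band numeric rasters only.
- Ellipsoidal (geodesic) buffering is not performed; buffers are planar in
  the chosen UTM zone, which is the method's accuracy model.
- Rotated rasters (ModelTransformation GeoTIFFs) are unsupported.
- Admin units may overlap; conservation of decomposed totals is only
  guaranteed for non-overlapping tilings.
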