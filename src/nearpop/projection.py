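"""Per-feature UTM zone selection and metric buffering.

Buffer distances are meters, so each hazard is buffered in the UTM zone
that fits it best: the zone containing its centroid longitude, in the
hemisphere of its centroid latitude. A hazard set spanning the continental
United States therefore spreads over the ten zones 10-19, each feature
using its own. After dilation the buffered geometries are reprojected back
to a single common CRS (lon/lat) so downstream overlay sees one system.

Latitudes poleward of ±84° keep the formula-derived zone (no polar
stereographic special case) and geometries crossing the antimeridian are
not supported; both are documented limitations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .crs import CRS, WGS84, transform_geom
from .errors import DomainError, SchemaError
from .geotable import GeoTable
from .io_prep import BUFFERED_PREFIX, BUFFER_DIST_PREFIX, prefixed_suffixes, validate_schema

#: segments per quarter circle used when dilating; 32 keeps the area of a
#: buffered point within 0.1% of the true circle.
QUAD_SEGS = 32


@dataclass(frozen=True)
class UtmZone:
    """One of the 60 UTM zones with its hemisphere and EPSG code."""

    zone: int
    hemisphere: str  # "north" | "south"

    @property
    def code(self) -> int:
        return (32600 if self.hemisphere == "north" else 32700) + self.zone

    @property
    def crs(self) -> CRS:
        return CRS(self.code)


def utm_for(lon: float, lat: float) -> UtmZone:
    """UTM zone for a lon/lat point: standard 6-degree bands with the
    zone-61 wraparound at the antimeridian; hemisphere from the latitude
    sign (lat = 0 counts as north)."""
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise DomainError(f"coordinates ({lon}, {lat}) outside lon/lat domain")
    zone = int(np.floor((lon + 180.0) / 6.0)) + 1
    if zone == 61:  # lon == 180 wraps to zone 1
        zone = 1
    return UtmZone(zone=zone, hemisphere="north" if lat >= 0 else "south")


def centroid_lonlat(geom: BaseGeometry, crs: CRS) -> tuple[float, float]:
    """Geometric centroid of ``geom`` expressed in lon/lat degrees."""
    if geom is None or geom.is_empty:
        raise DomainError("cannot take the centroid of an empty geometry")
    c = transform_geom(geom, crs, WGS84).centroid
    return (c.x, c.y)


def buffer_one(geom: BaseGeometry, crs: CRS, dist: float) -> BaseGeometry:
    """Dilate one geometry by ``dist`` meters in its best-fit UTM zone.

    The geometry is reprojected to the UTM zone of its centroid, buffered
    there, and reprojected back to the input CRS. A zero distance returns
    the geometry unchanged when it already has area (polygons); points and
    lines buffered by zero dilate to an empty polygon.
    """
    if dist < 0:
        raise DomainError(f"buffer distance must be non-negative, got {dist}")
    if geom is None or geom.is_empty:
        raise DomainError("cannot buffer an empty geometry")
    if dist == 0 and geom.area > 0:
        return geom
    lon, lat = centroid_lonlat(geom, crs)
    utm = utm_for(lon, lat).crs
    projected = transform_geom(geom, crs, utm)
    buffered = projected.buffer(dist, quad_segs=QUAD_SEGS)
    return transform_geom(buffered, utm, crs)


def buffer_hazards(hazards: GeoTable | None, out_crs: CRS = WGS84) -> GeoTable | None:
    """Buffer every hazard by every ``buffer_dist_<suffix>`` column.

    For each distance column the hazard's own distance is applied via
    :func:`buffer_one`, producing one ``buffered_hazard_<suffix>`` polygon
    column per input distance column, all in ``out_crs``. An empty input
    yields ``None`` (the empty marker).
    """
    if hazards is None or len(hazards) == 0:
        return None
    validate_schema(hazards, "hazard")
    suffixes = prefixed_suffixes(hazards.df, BUFFER_DIST_PREFIX)
    out = pd.DataFrame({"ID_hazard": hazards.df["ID_hazard"].to_numpy()})
    geoms = hazards.df["geometry"].to_numpy(dtype=object)
    ids = hazards.df["ID_hazard"].to_numpy()
    for sfx in suffixes:
        src_col = BUFFER_DIST_PREFIX if sfx == "" else f"{BUFFER_DIST_PREFIX}_{sfx}"
        dst_col = BUFFERED_PREFIX if sfx == "" else f"{BUFFERED_PREFIX}_{sfx}"
        dists = pd.to_numeric(hazards.df[src_col]).to_numpy(dtype=float)
        buffered = []
        for hid, geom, dist in zip(ids, geoms, dists):
            try:
                buf = buffer_one(geom, hazards.crs, float(dist))
            except Exception as exc:
                raise type(exc)(f"hazard {hid!r}: {exc}") from exc
            buffered.append(transform_geom(buf, hazards.crs, out_crs))
        out[dst_col] = buffered
    first = BUFFERED_PREFIX if suffixes[0] == "" else f"{BUFFERED_PREFIX}_{suffixes[0]}"
    return GeoTable(out, out_crs, geometry_column=first)
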