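"""Reading, writing, validating, and cleaning vector inputs.

Hazard and administrative-unit data enter as GeoJSON (RFC 7946) or
GeoParquet files in any supported CRS. On the way in, geometries are
repaired with a structure-preserving make-valid transform; rows whose
geometry is missing, empty, or unrepairable are dropped together with
their ID. A table left with no rows becomes ``None`` (the empty marker),
mirroring the estimator's "no admin data" state.

Column contract enforced by :func:`validate_schema`:

* hazards: string ``ID_hazard`` (unique, non-missing), ``geometry``, and
  one or more numeric, non-negative ``buffer_dist_<suffix>`` columns;
* admin units: string ``ID_admin_unit`` (unique, non-missing), ``geometry``;
* buffered hazards: ``ID_hazard`` plus one or more
  ``buffered_hazard_<suffix>`` geometry columns.

GeoJSON cannot represent several geometry columns, so when a buffered
hazard table is written to GeoJSON the secondary geometry columns are
stored as WKT strings in the feature properties and decoded again on read;
GeoParquet stores all geometry columns natively as WKB.
"""

from __future__ import annotations

import json
import math
import os
from typing import Optional

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .crs import CRS, WGS84
from .errors import CRSError, FormatError, GeoIOError, SchemaError
from .geotable import GeoTable, _is_geometry_column

BUFFER_DIST_PREFIX = "buffer_dist"
BUFFERED_PREFIX = "buffered_hazard"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_geo(path: str | os.PathLike) -> GeoTable:
    """Read a GeoJSON (``.geojson``/``.json``) or GeoParquet (``.parquet``)
    file into a :class:`GeoTable`.

    Raises
    ------
    FormatError
        If the extension is not one of the supported formats.
    GeoIOError
        If the file is absent or unreadable.
    CRSError
        If the file carries no usable CRS declaration.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".geojson", ".json"):
        return _read_geojson(path)
    if ext == ".parquet":
        return _read_geoparquet(path)
    raise FormatError(
        f"unsupported vector format {ext!r} for {path!r}; "
        "expected .geojson, .json, or .parquet"
    )


def write_geo(table: GeoTable, path: str | os.PathLike) -> None:
    """Write a :class:`GeoTable` as GeoJSON or GeoParquet by extension.

    GeoJSON output is always in lon/lat per the GeoJSON standard (the table
    is reprojected if needed); GeoParquet preserves the table's CRS.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".geojson", ".json"):
        _write_geojson(table, path)
    elif ext == ".parquet":
        _write_geoparquet(table, path)
    else:
        raise FormatError(f"unsupported vector format {ext!r} for {path!r}")


def _read_geojson(path: str) -> GeoTable:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise GeoIOError(f"cannot read {path!r}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path!r} is not valid GeoJSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path!r} is not a GeoJSON FeatureCollection")

    # RFC 7946 GeoJSON is implicitly WGS84 lon/lat; honor a legacy "crs"
    # member when present.
    crs = WGS84
    legacy = doc.get("crs")
    if legacy is not None:
        name = (legacy.get("properties") or {}).get("name")
        if name is None:
            raise CRSError(f"{path!r} has a crs member without a name")
        crs = CRS.from_user_input(name)

    rows = []
    geoms = []
    for feat in doc.get("features", []):
        props = dict(feat.get("properties") or {})
        g = feat.get("geometry")
        geoms.append(shape(g) if g is not None else None)
        rows.append(props)
    df = pd.DataFrame(rows) if rows else pd.DataFrame()
    df["geometry"] = geoms
    # decode secondary geometry columns stored as WKT properties
    for col in list(df.columns):
        if col != "geometry" and col.startswith(BUFFERED_PREFIX):
            df[col] = shapely.from_wkt(df[col].to_numpy(dtype=object))
    return GeoTable(df, crs)


def _write_geojson(table: GeoTable, path: str) -> None:
    table = table.to_crs(WGS84)
    geo_cols = table.geometry_columns()
    primary = table.geometry_column if table.geometry_column in geo_cols else geo_cols[0]
    features = []
    for _, row in table.df.iterrows():
        props = {}
        for col in table.df.columns:
            if col == primary:
                continue
            val = row[col]
            if isinstance(val, BaseGeometry):
                val = shapely.to_wkt(val, rounding_precision=-1)
            elif isinstance(val, (np.integer,)):
                val = int(val)
            elif isinstance(val, (np.floating,)):
                val = float(val)
            elif isinstance(val, float) and math.isnan(val):
                val = None
            props[col] = val
        geom = row[primary]
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(geom) if geom is not None else None,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    except OSError as exc:
        raise GeoIOError(f"cannot write {path!r}: {exc}") from exc


def _projjson_crs(crs: CRS) -> dict:
    return {"id": {"authority": "EPSG", "code": crs.epsg}}


def _read_geoparquet(path: str) -> GeoTable:
    try:
        pat = pq.read_table(path)
    except FileNotFoundError as exc:
        raise GeoIOError(f"cannot read {path!r}: {exc}") from exc
    except (pa.ArrowInvalid, OSError) as exc:
        raise GeoIOError(f"cannot read {path!r} as parquet: {exc}") from exc

    meta = pat.schema.metadata or {}
    if b"geo" not in meta:
        raise CRSError(
            f"{path!r} has no GeoParquet 'geo' metadata (no CRS declaration)"
        )
    geo = json.loads(meta[b"geo"])
    primary = geo.get("primary_column", "geometry")
    columns = geo.get("columns", {})
    if primary not in columns:
        raise FormatError(f"{path!r} GeoParquet metadata lacks the primary column")

    crs_spec = columns[primary].get("crs", "OGC:CRS84")
    if crs_spec is None:
        crs = WGS84  # GeoParquet: null crs means the default CRS84
    elif isinstance(crs_spec, dict):
        code = (crs_spec.get("id") or {}).get("code")
        if code is None:
            raise CRSError(f"{path!r}: cannot interpret PROJJSON CRS without an id")
        crs = CRS.from_user_input(int(code))
    else:
        crs = CRS.from_user_input(crs_spec)

    df = pat.to_pandas()
    for col in columns:
        if col in df.columns:
            df[col] = shapely.from_wkb(df[col].to_numpy(dtype=object))
    return GeoTable(df, crs, geometry_column=primary)


def _write_geoparquet(table: GeoTable, path: str) -> None:
    df = table.df.copy()
    geo_cols = table.geometry_columns()
    col_meta = {}
    for col in geo_cols:
        geoms = df[col].to_numpy(dtype=object)
        df[col] = [None if g is None else shapely.to_wkb(g) for g in geoms]
        types = sorted(
            {g.geom_type for g in geoms if isinstance(g, BaseGeometry) and not g.is_empty}
        )
        col_meta[col] = {
            "encoding": "WKB",
            "geometry_types": types,
            "crs": _projjson_crs(table.crs),
        }
    primary = table.geometry_column if table.geometry_column in geo_cols else geo_cols[0]
    geo = {
        "version": "1.0.0",
        "primary_column": primary,
        "columns": col_meta,
    }
    pat = pa.Table.from_pandas(df, preserve_index=False)
    pat = pat.replace_schema_metadata(
        {**(pat.schema.metadata or {}), b"geo": json.dumps(geo).encode()}
    )
    try:
        pq.write_table(pat, path)
    except OSError as exc:
        raise GeoIOError(f"cannot write {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _repair(geom) -> Optional[BaseGeometry]:
    """Make-valid repair; None when the geometry is missing, empty, or
    impossible to make valid."""
    if geom is None or (isinstance(geom, float) and math.isnan(geom)):
        return None
    if not isinstance(geom, BaseGeometry) or geom.is_empty:
        return None
    if geom.is_valid:
        return geom
    try:
        fixed = shapely.make_valid(geom)
    except Exception:
        return None
    if fixed is None or fixed.is_empty or not fixed.is_valid:
        return None
    return fixed


def clean_geometries(table: Optional[GeoTable]) -> Optional[GeoTable]:
    """Repair invalid geometries and drop unusable rows.

    Every geometry column is repaired with shapely's make-valid transform.
    A row is dropped when any of its geometry values is missing, empty, or
    cannot be repaired; its ID disappears with it. Returns ``None`` when no
    rows survive (or the input is ``None`` / empty). Idempotent.
    """
    if table is None or len(table) == 0:
        return None
    df = table.df.copy()
    geo_cols = [c for c in df.columns if _is_geometry_column(df[c])]
    if not geo_cols:
        geo_cols = [table.geometry_column] if table.geometry_column in df.columns else []
    if not geo_cols:
        raise SchemaError("table has no geometry column")
    keep = np.ones(len(df), dtype=bool)
    for col in geo_cols:
        repaired = [_repair(g) for g in df[col]]
        keep &= np.array([g is not None for g in repaired], dtype=bool)
        df[col] = repaired
    df = df.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        return None
    return GeoTable(df, table.crs, table.geometry_column)


# ---------------------------------------------------------------------------
# schema validation
# ---------------------------------------------------------------------------

def _check_id_column(df: pd.DataFrame, name: str) -> None:
    if name not in df.columns:
        raise SchemaError(f"missing required ID column {name!r}")
    ids = df[name]
    if ids.isna().any():
        raise SchemaError(f"{name!r} contains missing values")
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate {name!r} values: {dupes}")


def prefixed_suffixes(df: pd.DataFrame, prefix: str) -> list[str]:
    """Suffixes of the columns starting with ``prefix`` (``buffer_dist_main``
    -> ``main``; a bare ``buffer_dist`` yields an empty suffix)."""
    out = []
    for col in df.columns:
        if col == prefix:
            out.append("")
        elif col.startswith(prefix + "_"):
            out.append(col[len(prefix) + 1 :])
    return out


def validate_schema(table: GeoTable, kind: str) -> None:
    """Validate the column contract for ``kind`` in {hazard, admin, buffered}.

    Raises :class:`SchemaError` naming the offending columns or IDs;
    returns ``None`` on success.
    """
    if table is None or len(table) == 0:
        raise SchemaError("cannot validate an empty table")
    df = table.df
    if kind == "hazard":
        _check_id_column(df, "ID_hazard")
        suffixes = prefixed_suffixes(df, BUFFER_DIST_PREFIX)
        if not suffixes:
            raise SchemaError(
                "hazard table needs at least one column starting with "
                f"{BUFFER_DIST_PREFIX!r}"
            )
        if len(set(suffixes)) != len(suffixes):
            raise SchemaError("buffer_dist column suffixes are not unique")
        for sfx in suffixes:
            col = BUFFER_DIST_PREFIX if sfx == "" else f"{BUFFER_DIST_PREFIX}_{sfx}"
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise SchemaError(f"{col!r} contains non-numeric or missing values")
            if (vals < 0).any():
                raise SchemaError(f"{col!r} contains negative buffer distances")
        if "geometry" not in df.columns:
            raise SchemaError("hazard table has no 'geometry' column")
    elif kind == "admin":
        _check_id_column(df, "ID_admin_unit")
        if "geometry" not in df.columns:
            raise SchemaError("admin table has no 'geometry' column")
    elif kind == "buffered":
        _check_id_column(df, "ID_hazard")
        suffixes = prefixed_suffixes(df, BUFFERED_PREFIX)
        if not suffixes:
            raise SchemaError(
                "buffered table needs at least one column starting with "
                f"{BUFFERED_PREFIX!r}"
            )
        if len(set(suffixes)) != len(suffixes):
            raise SchemaError("buffered_hazard column suffixes are not unique")
    else:
        raise ValueError(f"unknown schema kind {kind!r}")
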