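"""Exposure and denominator estimation.

This is the orchestration layer tying buffered hazards, administrative
units, and the population raster together. Exposed-population counts come
in four modes, the cross of two choices:

* hazard-specific (one count per hazard; people near several hazards are
  counted in each) versus cumulative (buffered geometries are merged into
  a single union per buffer column, so each person is counted once);
* with or without administrative units (with units, counts are taken over
  the intersection of each buffered geometry — or the union — with each
  unit, yielding per-unit rows).

``est_total_pop`` computes matching denominators: the population residing
in each administrative unit according to the same raster and the same
partial-pixel apportionment, so numerator and denominator are consistent.

Counts are reported as real numbers; partial-pixel weighting is inherently
fractional and rounding is left to the caller.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import shapely

from .crs import CRS
from .errors import SchemaError
from .geotable import GeoTable
from . import io_prep
from .io_prep import BUFFERED_PREFIX, prefixed_suffixes, validate_schema
from .projection import buffer_hazards
from .raster import PopulationRaster
from .zonal import masked_sum


def _buffered_columns(buffered: GeoTable) -> dict[str, str]:
    """Map suffix -> buffered_hazard column name (suffix '' for the bare
    prefix), preserving column order."""
    out = {}
    for sfx in prefixed_suffixes(buffered.df, BUFFERED_PREFIX):
        col = BUFFERED_PREFIX if sfx == "" else f"{BUFFERED_PREFIX}_{sfx}"
        out[sfx] = col
    return out


def _exposed_name(suffix: str) -> str:
    return "exposed" if suffix == "" else f"exposed_{suffix}"


def union_per_column(buffered: GeoTable, suffix: str):
    """Union of all geometries in ``buffered_hazard_<suffix>``; columns are
    merged independently of each other."""
    col = BUFFERED_PREFIX if suffix == "" else f"{BUFFERED_PREFIX}_{suffix}"
    if col not in buffered.df.columns:
        raise SchemaError(f"no column {col!r} in buffered table")
    return shapely.union_all(buffered.df[col].to_numpy(dtype=object))


def group_components(geometries) -> list[list[int]]:
    """Partition geometries into connected components of the pairwise
    *intersects* relation (bounding boxes only prefilter candidate pairs).

    Returns index groups; extraction can proceed per group with its own
    raster window.
    """
    geoms = list(geometries)
    n = len(geoms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    tree = shapely.STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j > i and shapely.intersects(g, geoms[j]):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def est_exposed_pop(
    buffered: GeoTable,
    hazard_specific: bool,
    raster: PopulationRaster,
    admin: Optional[GeoTable] = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Exposed population per the four usage modes.

    Parameters
    ----------
    buffered
        Buffered hazard table: ``ID_hazard`` plus one or more
        ``buffered_hazard_<suffix>`` polygon columns.
    hazard_specific
        ``True`` for one count per hazard (double counting allowed across
        hazards); ``False`` for cumulative counts over the per-column union.
    raster
        Open population raster.
    admin
        Optional cleaned administrative-unit table; when given, counts are
        decomposed by unit.
    all_pairs
        Hazard-specific x admin mode only: emit every hazard x unit pair
        rather than only pairs whose bounding boxes intersect (the omitted
        pairs are exact zeros either way).

    Returns
    -------
    pandas.DataFrame
        One ``exposed_<suffix>`` column per buffered column; rows keyed by
        ``ID_hazard`` and/or ``ID_admin_unit`` depending on mode.
    """
    validate_schema(buffered, "buffered")
    columns = _buffered_columns(buffered)
    ids = buffered.df["ID_hazard"].to_numpy()

    if admin is None:
        if hazard_specific:
            data = {"ID_hazard": ids}
            for sfx, col in columns.items():
                geoms = buffered.df[col].to_numpy(dtype=object)
                data[_exposed_name(sfx)] = [
                    masked_sum(g, raster, buffered.crs) for g in geoms
                ]
            return pd.DataFrame(data)
        # cumulative: union per column, extracted per connected component so
        # each component keeps its own raster window
        row = {}
        for sfx, col in columns.items():
            geoms = list(buffered.df[col].to_numpy(dtype=object))
            total = 0.0
            for group in group_components(geoms):
                merged = shapely.union_all([geoms[i] for i in group])
                total += masked_sum(merged, raster, buffered.crs)
            row[_exposed_name(sfx)] = total
        return pd.DataFrame([row])

    validate_schema(admin, "admin")
    admin = admin.to_crs(buffered.crs)
    admin_ids = admin.df["ID_admin_unit"].to_numpy()
    admin_geoms = admin.df["geometry"].to_numpy(dtype=object)

    if hazard_specific:
        rows = []
        for hi, hid in enumerate(ids):
            hazard_geoms = {sfx: buffered.df[col].to_numpy(dtype=object)[hi]
                            for sfx, col in columns.items()}
            # candidate units: bbox intersection with any buffer column
            for ai, aid in enumerate(admin_ids):
                if not all_pairs:
                    abox = shapely.box(*shapely.bounds(admin_geoms[ai]))
                    if not any(
                        shapely.intersects(abox, shapely.box(*shapely.bounds(g)))
                        for g in hazard_geoms.values()
                    ):
                        continue
                row = {"ID_hazard": hid, "ID_admin_unit": aid}
                for sfx, g in hazard_geoms.items():
                    inter = shapely.intersection(g, admin_geoms[ai])
                    row[_exposed_name(sfx)] = masked_sum(inter, raster, buffered.crs)
                rows.append(row)
        cols_out = ["ID_hazard", "ID_admin_unit"] + [_exposed_name(s) for s in columns]
        return pd.DataFrame(rows, columns=cols_out)

    # cumulative by admin unit
    unions = {sfx: union_per_column(buffered, sfx) for sfx in columns}
    rows = []
    for ai, aid in enumerate(admin_ids):
        row = {"ID_admin_unit": aid}
        for sfx, merged in unions.items():
            inter = shapely.intersection(merged, admin_geoms[ai])
            row[_exposed_name(sfx)] = masked_sum(inter, raster, buffered.crs)
        rows.append(row)
    cols_out = ["ID_admin_unit"] + [_exposed_name(s) for s in columns]
    return pd.DataFrame(rows, columns=cols_out)


def est_total_pop(
    admin: Optional[GeoTable], raster: PopulationRaster
) -> Optional[pd.DataFrame]:
    """Population residing in each administrative unit, by the same
    partial-pixel apportionment as the exposure counts. Returns ``None``
    for an absent/empty admin table (the empty marker)."""
    if admin is None or len(admin) == 0:
        return None
    validate_schema(admin, "admin")
    geoms = admin.df["geometry"].to_numpy(dtype=object)
    pops = [masked_sum(g, raster, admin.crs) for g in geoms]
    return pd.DataFrame(
        {"ID_admin_unit": admin.df["ID_admin_unit"].to_numpy(), "population": pops}
    )


class PopEstimator:
    """Convenience facade bundling the pipeline: read and clean inputs,
    buffer hazards, and compute exposure counts and denominators.

    Parameters
    ----------
    pop_path
        Path to the population GeoTIFF (optional; may instead be passed to
        the estimation methods).
    admin_path
        Path to administrative-unit GeoJSON/GeoParquet (optional). The file
        is read and cleaned immediately; if nothing survives cleaning the
        ``admin_data`` attribute is ``None``.
    """

    def __init__(self, pop_path: str | None = None, admin_path: str | None = None):
        self.pop_path = pop_path
        self.admin_data: Optional[GeoTable] = None
        if admin_path is not None:
            self.admin_data = io_prep.clean_geometries(io_prep.read_geo(admin_path))

    def _raster(self, pop_path: str | None) -> PopulationRaster:
        path = pop_path or self.pop_path
        if path is None:
            raise ValueError("no population raster: pass pop_path")
        return PopulationRaster(path)

    def prep_data(self, hazard_path: str) -> Optional[GeoTable]:
        """Read, clean, and buffer a hazard file into a buffered table."""
        hazards = io_prep.clean_geometries(io_prep.read_geo(hazard_path))
        return buffer_hazards(hazards)

    def est_exposed_pop(
        self,
        hazards: GeoTable,
        hazard_specific: bool,
        pop_path: str | None = None,
        all_pairs: bool = False,
    ) -> pd.DataFrame:
        with self._raster(pop_path) as raster:
            return est_exposed_pop(
                hazards, hazard_specific, raster, self.admin_data, all_pairs=all_pairs
            )

    def est_total_pop(self, pop_path: str | None = None) -> Optional[pd.DataFrame]:
        with self._raster(pop_path) as raster:
            return est_total_pop(self.admin_data, raster)
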