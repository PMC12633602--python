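"""A minimal vector feature table: pandas DataFrame + shapely geometries + CRS.

This is the in-memory container behind every vector input and output in
nearpop (hazards, buffered hazards, administrative units). It is
deliberately small: a DataFrame whose geometry-valued columns hold shapely
objects, plus a single CRS shared by all geometry columns. Tables may carry
several geometry columns (a buffered hazard table has one polygon column
per buffer specification).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .crs import CRS, transform_geoms
from .errors import CRSError


def _is_geometry_column(series: pd.Series) -> bool:
    if series.dtype != object:
        return False
    for v in series:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        return isinstance(v, BaseGeometry)
    return False


class GeoTable:
    """A feature table with a declared CRS.

    Parameters
    ----------
    df
        The attribute data, including one or more columns of shapely
        geometries. A copy is not made; callers should not mutate `df`
        afterwards.
    crs
        The coordinate reference system of every geometry column.
    geometry_column
        Name of the primary geometry column (default ``"geometry"``).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        crs: CRS | int | str,
        geometry_column: str = "geometry",
    ) -> None:
        if crs is None:
            raise CRSError("a GeoTable requires a declared CRS")
        self.df = df
        self.crs = CRS.from_user_input(crs)
        self.geometry_column = geometry_column

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def geometry(self) -> pd.Series:
        return self.df[self.geometry_column]

    def geometry_columns(self) -> list[str]:
        """Names of all geometry-valued columns, primary first."""
        cols = [c for c in self.df.columns if _is_geometry_column(self.df[c])]
        if self.geometry_column in cols:
            cols.remove(self.geometry_column)
            cols.insert(0, self.geometry_column)
        return cols

    def copy(self) -> "GeoTable":
        return GeoTable(self.df.copy(), self.crs, self.geometry_column)

    # -- CRS ---------------------------------------------------------------
    def to_crs(self, crs: CRS | int | str) -> "GeoTable":
        """Return a table with every geometry column reprojected to `crs`."""
        dst = CRS.from_user_input(crs)
        if dst == self.crs:
            return self
        df = self.df.copy()
        for col in self.geometry_columns():
            df[col] = transform_geoms(df[col].to_numpy(), self.crs, dst)
        return GeoTable(df, dst, self.geometry_column)

    # -- convenience -------------------------------------------------------
    @classmethod
    def from_features(
        cls,
        ids: Iterable[str],
        geometries: Iterable[BaseGeometry],
        crs: CRS | int | str,
        id_column: str = "ID_hazard",
        **extra_columns,
    ) -> "GeoTable":
        df = pd.DataFrame({id_column: list(ids)})
        df["geometry"] = list(geometries)
        for name, values in extra_columns.items():
            df[name] = values
        return cls(df, crs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GeoTable [{len(self)} rows, CRS {self.crs}, "
            f"geometry columns {self.geometry_columns()}]>"
        )


def geoms_equal(a: BaseGeometry, b: BaseGeometry, tol: float = 1e-9) -> bool:
    """Geometry equality within a coordinate tolerance (order-insensitive)."""
    return bool(shapely.equals_exact(shapely.normalize(a), shapely.normalize(b), tolerance=tol))
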