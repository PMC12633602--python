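"""Synthetic rasters, hazards, and admin tilings with known answers.

Everything here is deterministic given its arguments (random fills are
driven by an explicit seed) and grid-aligned, so zonal and estimator
results admit closed-form expected values. The default fixture CRS is a
metric UTM zone (EPSG:32611) anchored near its central meridian with
100 m cells — the resolution class of common gridded population products —
so buffer distances in meters act directly on grid coordinates; a lon/lat
variant exercises the UTM buffering path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .crs import CRS
from .errors import DomainError
from .geotable import GeoTable
from .raster import GridTransform, PopulationRaster, write_raster

#: default anchor: easting 500 km (the central meridian), northing ~34°N
DEFAULT_ORIGIN = (500_000.0, 3_800_000.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry of a synthetic raster grid.

    ``origin`` is the CRS coordinate of the grid's top-left corner;
    ``fill`` is ``("uniform", v)``, ``("random", seed)`` (uniform [0, 100)
    person counts), or ``("ramp",)`` (value = row index).
    """

    grid_shape: tuple[int, int] = (20, 20)  # rows, cols
    cell_size: float = 100.0
    origin: tuple[float, float] = DEFAULT_ORIGIN
    fill: tuple = ("uniform", 1.0)
    crs: CRS = field(default_factory=lambda: CRS(32611))

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1 or self.cell_size <= 0:
            raise DomainError("grid_shape must be >= 1x1 and cell_size > 0")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(
            x0=self.origin[0], y0=self.origin[1],
            dx=self.cell_size, dy=-self.cell_size,
        )

    def values(self) -> np.ndarray:
        rows, cols = self.grid_shape
        kind = self.fill[0]
        if kind == "uniform":
            return np.full((rows, cols), float(self.fill[1]))
        if kind == "random":
            rng = np.random.default_rng(int(self.fill[1]))
            return rng.uniform(0.0, 100.0, size=(rows, cols))
        if kind == "ramp":
            return np.tile(np.arange(rows, dtype=float)[:, None], (1, cols))
        raise DomainError(f"unknown fill {kind!r}")

    def cell_box(self, r0: int, r1: int, c0: int, c1: int):
        """Polygon of the half-open cell-index box ``[r0:r1, c0:c1]``."""
        t = self.transform
        return shapely.box(
            t.x0 + c0 * t.dx, t.y0 + r1 * t.dy,
            t.x0 + c1 * t.dx, t.y0 + r0 * t.dy,
        )


def make_raster(spec: FixtureSpec, path, nodata: float | None = None) -> PopulationRaster:
    """Write the spec's grid to ``path`` as GeoTIFF and open it."""
    write_raster(path, spec.values(), spec.transform, spec.crs, nodata=nodata)
    return PopulationRaster(path)


def make_rect_hazards(
    spec: FixtureSpec,
    rects: Sequence[tuple[int, int, int, int]],
    ids: Sequence[str] | None = None,
    buffer: float = 0.0,
) -> GeoTable | None:
    """Grid-aligned rectangular hazards.

    Each rect is a half-open cell-index box ``(r0, r1, c0, c1)``; IDs
    default to ``haz_<k>``. A ``buffer_dist_main`` column is set to
    ``buffer`` meters for every row. Empty ``rects`` gives ``None``.
    """
    if not rects:
        return None
    rows, cols = spec.grid_shape
    geoms = []
    for r0, r1, c0, c1 in rects:
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise DomainError(f"box {(r0, r1, c0, c1)} outside the {rows}x{cols} grid")
        geoms.append(spec.cell_box(r0, r1, c0, c1))
    if ids is None:
        ids = [f"haz_{k}" for k in range(len(rects))]
    df = pd.DataFrame({"ID_hazard": list(ids)})
    df["geometry"] = geoms
    df["buffer_dist_main"] = float(buffer)
    return GeoTable(df, spec.crs)


def make_admin_tiling(spec: FixtureSpec, nx: int, ny: int) -> GeoTable:
    """``nx`` x ``ny`` rectangles exactly tiling the raster extent.

    ``nx`` must divide the column count and ``ny`` the row count, so every
    tile covers a whole number of cells. IDs are ``admin_<i>_<j>`` with
    ``i`` the column block and ``j`` the row block.
    """
    rows, cols = spec.grid_shape
    if nx < 1 or ny < 1 or cols % nx or rows % ny:
        raise DomainError(
            f"{nx}x{ny} tiling does not divide the {rows}x{cols} grid"
        )
    ids, geoms = [], []
    rstep, cstep = rows // ny, cols // nx
    for j in range(ny):
        for i in range(nx):
            ids.append(f"admin_{i}_{j}")
            geoms.append(
                spec.cell_box(j * rstep, (j + 1) * rstep, i * cstep, (i + 1) * cstep)
            )
    df = pd.DataFrame({"ID_admin_unit": ids})
    df["geometry"] = geoms
    return GeoTable(df, spec.crs)
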