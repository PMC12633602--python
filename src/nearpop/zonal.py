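"""Exact area-weighted raster extraction.

The apportionment rule: a raster cell contributes its value times the
exact fraction of its area covered by the polygon. A cell of 100 people
half inside the polygon contributes 50. Fractions come from exact
axis-aligned clipping of the polygon against each candidate cell
rectangle — cells strictly inside the polygon get fraction 1 without
clipping; only boundary cells are clipped. This assumes population is
uniform within a cell, the standard assumption for gridded products.

Extraction is windowed: only the raster cells inside the polygon's
(padded) bounding box are considered and read, so memory scales with the
polygon's footprint, not with the raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .crs import CRS, transform_geom
from .errors import CRSError
from .raster import PopulationRaster

#: row-block height used when clipping very tall windows, bounding the
#: number of cell rectangles alive at once.
_BLOCK_ROWS = 512

_CLAMP_TOL = 1e-9


@dataclass
class CoverageVector:
    """Sparse per-cell coverage fractions for one polygon.

    ``rows``/``cols`` are cell indices into the raster grid and ``fracs``
    the covered-area fraction of each listed cell, in ``[0, 1]``.
    ``window`` is the half-open cell-index box ``(r0, r1, c0, c1)`` that
    was scanned (``None`` for an empty vector).
    """

    rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fracs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    window: tuple[int, int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.fracs)

    def covered_area(self, cell_area: float) -> float:
        """Total covered area implied by the fractions."""
        return float(self.fracs.sum() * cell_area)


def cell_coverage(
    polygon: shapely.geometry.base.BaseGeometry,
    raster: PopulationRaster,
    polygon_crs: CRS | None = None,
) -> CoverageVector:
    """Exact covered-area fraction of every raster cell the polygon touches.

    ``polygon`` must be in the raster CRS; pass ``polygon_crs`` to assert
    it (a mismatch raises :class:`CRSError`). Cells outside the raster
    extent are omitted. An empty polygon gives an empty vector.
    """
    if polygon_crs is not None and polygon_crs != raster.crs:
        raise CRSError(
            f"polygon CRS {polygon_crs} does not match raster CRS {raster.crs}"
        )
    if polygon is None or polygon.is_empty:
        return CoverageVector()

    t = raster.transform
    nrows, ncols = raster.shape
    win = t.window_for_bounds(*polygon.bounds, rows=nrows, cols=ncols, pad=1)
    if win is None:
        return CoverageVector()
    r0, r1, c0, c1 = win

    cell_area = t.cell_area
    out_rows: list[np.ndarray] = []
    out_cols: list[np.ndarray] = []
    out_fracs: list[np.ndarray] = []

    prepared = polygon
    shapely.prepare(prepared)

    for br0 in range(r0, r1, _BLOCK_ROWS):
        br1 = min(br0 + _BLOCK_ROWS, r1)
        rr, cc = np.meshgrid(np.arange(br0, br1), np.arange(c0, c1), indexing="ij")
        rr = rr.ravel()
        cc = cc.ravel()
        x_lo = t.x0 + cc * t.dx
        y_hi = t.y0 + rr * t.dy
        boxes = shapely.box(x_lo, y_hi + t.dy, x_lo + t.dx, y_hi)

        touches = shapely.intersects(prepared, boxes)
        if not touches.any():
            continue
        rr, cc, boxes = rr[touches], cc[touches], boxes[touches]
        inside = shapely.contains_properly(prepared, boxes)
        fracs = np.ones(len(boxes), dtype=float)
        edge = ~inside
        if edge.any():
            clipped = shapely.intersection(polygon, boxes[edge])
            fracs[edge] = shapely.area(clipped) / cell_area
        over = fracs - 1.0
        if (over > _CLAMP_TOL).any() or (fracs < -_CLAMP_TOL).any():
            raise AssertionError("cell coverage fraction left [0, 1] beyond tolerance")
        np.clip(fracs, 0.0, 1.0, out=fracs)
        keep = fracs > 0.0
        out_rows.append(rr[keep])
        out_cols.append(cc[keep])
        out_fracs.append(fracs[keep])

    if not out_rows:
        return CoverageVector(window=win)
    return CoverageVector(
        rows=np.concatenate(out_rows),
        cols=np.concatenate(out_cols),
        fracs=np.concatenate(out_fracs),
        window=win,
    )


def weighted_sum(raster: PopulationRaster, cov: CoverageVector) -> float:
    """Coverage-weighted population sum: sum of value(cell) x fraction(cell),
    with nodata cells contributing zero."""
    if len(cov) == 0:
        return 0.0
    nrows, ncols = raster.shape
    if (
        cov.rows.min() < 0 or cov.rows.max() >= nrows
        or cov.cols.min() < 0 or cov.cols.max() >= ncols
    ):
        raise IndexError("coverage entries outside the raster grid")
    r0, r1 = int(cov.rows.min()), int(cov.rows.max()) + 1
    c0, c1 = int(cov.cols.min()), int(cov.cols.max()) + 1
    window = raster.read_window(r0, r1, c0, c1)
    vals = raster.values_with_nodata_zeroed(window)
    return float((vals[cov.rows - r0, cov.cols - c0] * cov.fracs).sum())


def masked_sum(
    polygon: shapely.geometry.base.BaseGeometry,
    raster: PopulationRaster,
    polygon_crs: CRS | None = None,
) -> float:
    """People inside ``polygon``: reproject it to the raster CRS if needed,
    then take the coverage-weighted sum over its windowed cells."""
    if polygon is None or polygon.is_empty:
        return 0.0
    if polygon_crs is not None and polygon_crs != raster.crs:
        polygon = transform_geom(polygon, polygon_crs, raster.crs)
    return weighted_sum(raster, cell_coverage(polygon, raster))
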