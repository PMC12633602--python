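"""Gridded population rasters (GeoTIFF).

A population raster is a regular grid whose cell values are resident
counts per cell (persons). This module opens GeoTIFFs, exposes the affine
grid transform, CRS and nodata sentinel, and reads rectangular windows of
cells without materializing the whole band — windows are assembled from
only the TIFF tiles (or strips) they touch, so the working set scales with
the window, not the raster.

Georeferencing is taken from the standard GeoTIFF tags: ModelPixelScale
(33550) + ModelTiepoint (33922) for the affine transform, the
GeoKeyDirectory (34735) for the CRS, and GDAL_NODATA (42113) for the
nodata value. ModelTransformation rasters (rotated grids) are not
supported. Band 1 is the population band.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

from .crs import CRS
from .errors import CRSError, FormatError, GeoIOError

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_NODATA = 42113

_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_TYPE = 3072


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid: ``x = x0 + col*dx``, ``y = y0 + row*dy``
    with ``dx > 0`` and ``dy < 0`` (``(x0, y0)`` is the top-left corner)."""

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise FormatError("raster transform has zero cell size")

    @property
    def cell_area(self) -> float:
        return abs(self.dx * self.dy)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x1 = self.x0 + col * self.dx
        y1 = self.y0 + (row + 1) * self.dy
        return (x1, y1, x1 + self.dx, self.y0 + row * self.dy)

    def window_for_bounds(
        self, minx: float, miny: float, maxx: float, maxy: float,
        rows: int, cols: int, pad: int = 1,
    ) -> tuple[int, int, int, int] | None:
        """Cell-index window ``(r0, r1, c0, c1)`` (half-open) covering the
        given CRS bounds, padded by ``pad`` whole cells and clipped to the
        grid; ``None`` when the bounds miss the grid entirely."""
        c0 = int(np.floor((minx - self.x0) / self.dx)) - pad
        c1 = int(np.ceil((maxx - self.x0) / self.dx)) + pad
        r0 = int(np.floor((maxy - self.y0) / self.dy)) - pad
        r1 = int(np.ceil((miny - self.y0) / self.dy)) + pad
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        if r0 >= r1 or c0 >= c1:
            return None
        return (r0, r1, c0, c1)


def _parse_geokeys(values) -> CRS:
    vals = [int(v) for v in values]
    if len(vals) < 4:
        raise CRSError("malformed GeoKeyDirectory tag")
    nkeys = vals[3]
    keys = {}
    for i in range(nkeys):
        kid, loc, cnt, val = vals[4 + 4 * i : 8 + 4 * i]
        if loc == 0:
            keys[kid] = val
    if _KEY_PROJECTED_TYPE in keys:
        return CRS(keys[_KEY_PROJECTED_TYPE])
    if keys.get(_KEY_MODEL_TYPE) == 2 or _KEY_GEOGRAPHIC_TYPE in keys:
        code = keys.get(_KEY_GEOGRAPHIC_TYPE, 4326)
        return CRS(code)
    raise CRSError("GeoTIFF declares no recognizable CRS")


class PopulationRaster:
    """An open population GeoTIFF.

    Use as a context manager or call :meth:`close` when done. ``nodata``
    cells contribute zero persons to any sum.
    """

    def __init__(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        try:
            self._tif = tifffile.TiffFile(path)
        except (OSError, tifffile.TiffFileError) as exc:
            raise GeoIOError(f"cannot open raster {path!r}: {exc}") from exc
        self.path = path
        page = self._tif.pages[0]
        self._page = page
        self.shape = (page.imagelength, page.imagewidth)
        self.dtype = page.dtype

        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            self._tif.close()
            raise FormatError(
                f"{path!r} lacks GeoTIFF ModelPixelScale/ModelTiepoint tags"
            )
        sx, sy = float(scale.value[0]), float(scale.value[1])
        i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
        # tiepoint maps raster point (i, j) to model point (x, y)
        self.transform = GridTransform(x0=x - i * sx, y0=y + j * sy, dx=sx, dy=-sy)

        geokeys = tags.get(_TAG_GEOKEYS)
        if geokeys is None:
            self._tif.close()
            raise CRSError(f"{path!r} has no GeoKeyDirectory (no CRS)")
        self.crs = _parse_geokeys(geokeys.value)

        nod = tags.get(_TAG_NODATA)
        self.nodata: float | None = None
        if nod is not None:
            text = nod.value
            if isinstance(text, bytes):
                text = text.decode("ascii", "ignore")
            text = str(text).strip().strip("\x00")
            if text and text.lower() != "none":
                self.nodata = float(text)

        self._full_cache: np.ndarray | None = None

    # -- lifecycle ---------------------------------------------------------
    def close(self) -> None:
        self._tif.close()

    def __enter__(self) -> "PopulationRaster":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- reading -----------------------------------------------------------
    def read_window(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        """Read cells ``[r0:r1, c0:c1]`` (half-open). Only the TIFF
        segments overlapping the window are decoded."""
        rows, cols = self.shape
        if not (0 <= r0 <= r1 <= rows and 0 <= c0 <= c1 <= cols):
            raise IndexError(
                f"window ({r0},{r1},{c0},{c1}) outside raster {self.shape}"
            )
        if r0 == r1 or c0 == c1:
            return np.empty((r1 - r0, c1 - c0), dtype=self.dtype)
        if self._full_cache is not None:
            return self._full_cache[r0:r1, c0:c1]

        page = self._page
        th = page.tilelength or page.rowsperstrip or rows
        tw = page.tilewidth or cols
        out = np.zeros((r1 - r0, c1 - c0), dtype=self.dtype)
        tiles_across = (cols + tw - 1) // tw
        fh = self._tif.filehandle
        decode = page.decode
        for ti in range(r0 // th, (r1 - 1) // th + 1):
            for tj in range(c0 // tw, (c1 - 1) // tw + 1):
                idx = ti * tiles_across + tj
                if idx >= len(page.dataoffsets):
                    continue
                nbytes = page.databytecounts[idx]
                if nbytes == 0:
                    continue
                fh.seek(page.dataoffsets[idx])
                data = fh.read(nbytes)
                segment, _, seg_shape = decode(data, idx)
                seg = np.asarray(segment).reshape(seg_shape[-3], seg_shape[-2])
                tr0, tc0 = ti * th, tj * tw
                sr0, sr1 = max(r0, tr0), min(r1, min(tr0 + th, rows))
                sc0, sc1 = max(c0, tc0), min(c1, min(tc0 + tw, cols))
                out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = seg[
                    sr0 - tr0 : sr1 - tr0, sc0 - tc0 : sc1 - tc0
                ]
        return out

    def read_all(self) -> np.ndarray:
        """Read (and cache) the full band. Used for totals on small rasters
        and as a fallback; extraction paths use :meth:`read_window`."""
        if self._full_cache is None:
            self._full_cache = self._page.asarray()
        return self._full_cache

    def values_with_nodata_zeroed(self, window: np.ndarray) -> np.ndarray:
        """Window values as float with nodata/NaN replaced by 0.

        Raises ``ValueError`` on negative population values, which a person
        count cannot contain.
        """
        vals = window.astype(float, copy=True)
        if self.nodata is not None:
            vals[window == self.nodata] = 0.0
        vals[np.isnan(vals)] = 0.0
        if (vals < 0).any():
            raise ValueError("population raster contains negative cell values")
        return vals

    def total_population(self, block_rows: int = 1024) -> float:
        """Sum of all (nodata-zeroed) cell values, streamed by row blocks."""
        rows, cols = self.shape
        total = 0.0
        for r0 in range(0, rows, block_rows):
            r1 = min(r0 + block_rows, rows)
            total += float(
                self.values_with_nodata_zeroed(self.read_window(r0, r1, 0, cols)).sum()
            )
        return total

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        t = self.transform
        rows, cols = self.shape
        return (t.x0, t.y0 + rows * t.dy, t.x0 + cols * t.dx, t.y0)


def write_raster(
    path: str | os.PathLike,
    values: np.ndarray,
    transform: GridTransform,
    crs: CRS,
    nodata: float | None = None,
    tile: tuple[int, int] | None = (64, 64),
) -> None:
    """Write a single-band GeoTIFF with the given grid and CRS.

    Output is uncompressed and (by default) tiled so windowed reads touch
    only the tiles a window overlaps.
    """
    values = np.ascontiguousarray(values)
    if values.ndim != 2:
        raise FormatError("raster values must be a 2-D array")
    if crs.is_geographic:
        geokeys = (1, 1, 0, 3,
                   _KEY_MODEL_TYPE, 0, 1, 2,
                   _KEY_RASTER_TYPE, 0, 1, 1,
                   _KEY_GEOGRAPHIC_TYPE, 0, 1, 4326)
    else:
        geokeys = (1, 1, 0, 3,
                   _KEY_MODEL_TYPE, 0, 1, 1,
                   _KEY_RASTER_TYPE, 0, 1, 1,
                   _KEY_PROJECTED_TYPE, 0, 1, crs.epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, -transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
    ]
    if nodata is not None:
        extratags.append((_TAG_NODATA, "s", 0, repr(float(nodata))))
    kwargs = {}
    if tile is not None and values.shape[0] >= 16 and values.shape[1] >= 16:
        kwargs["tile"] = tile
    try:
        tifffile.imwrite(os.fspath(path), values, extratags=extratags, **kwargs)
    except OSError as exc:
        raise GeoIOError(f"cannot write raster {path!r}: {exc}") from exc
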