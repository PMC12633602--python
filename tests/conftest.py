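import numpy as np
import pytest

from nearpop import CRS, FixtureSpec, make_raster


@pytest.fixture(scope="session")
def metric_spec() -> FixtureSpec:
    """20x20 grid of 100 m cells in EPSG:32611, uniform 1 person/cell."""
    return FixtureSpec(grid_shape=(20, 20), cell_size=100.0, fill=("uniform", 1.0))


@pytest.fixture(scope="session")
def uniform_raster(metric_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("rasters") / "uniform.tif"
    with make_raster(metric_spec, path) as raster:
        yield raster


@pytest.fixture(scope="session")
def random_spec() -> FixtureSpec:
    return FixtureSpec(grid_shape=(20, 20), cell_size=100.0, fill=("random", 7))


@pytest.fixture(scope="session")
def random_raster(random_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("rasters") / "random.tif"
    with make_raster(random_spec, path) as raster:
        yield raster


@pytest.fixture(scope="session")
def lonlat_spec() -> FixtureSpec:
    """Small geographic-grid fixture (cells in degrees) exercising the
    reprojection path: polygon CRS != raster CRS."""
    return FixtureSpec(
        grid_shape=(10, 10),
        cell_size=0.001,
        origin=(-118.7, 34.0),
        fill=("uniform", 2.0),
        crs=CRS(4326),
    )


@pytest.fixture(scope="session")
def lonlat_raster(lonlat_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("rasters") / "lonlat.tif"
    with make_raster(lonlat_spec, path) as raster:
        yield raster


def random_simple_polygon(rng: np.random.Generator, bounds, n_vertices: int = 12):
    """A random star-shaped (hence simple) polygon inside ``bounds``."""
    from shapely.geometry import Polygon

    minx, miny, maxx, maxy = bounds
    cx = rng.uniform(minx + 0.3 * (maxx - minx), maxx - 0.3 * (maxx - minx))
    cy = rng.uniform(miny + 0.3 * (maxy - miny), maxy - 0.3 * (maxy - miny))
    rmax = 0.45 * min(maxx - minx, maxy - miny)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(0.2 * rmax, rmax, size=n_vertices)
    pts = [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]
    return Polygon(pts)


def subsample_coverage(polygon, raster, samples_per_side: int = 20):
    """Monte-Carlo oracle for per-cell coverage fractions: a regular
    subgrid of ``samples_per_side**2`` points per cell, fraction = share of
    points inside the polygon. Independent of the clipping implementation.
    """
    import shapely

    t = raster.transform
    nrows, ncols = raster.shape
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(np.floor((minx - t.x0) / t.dx)) - 1, 0)
    c1 = min(int(np.ceil((maxx - t.x0) / t.dx)) + 1, ncols)
    r0 = max(int(np.floor((maxy - t.y0) / t.dy)) - 1, 0)
    r1 = min(int(np.ceil((miny - t.y0) / t.dy)) + 1, nrows)
    offs = (np.arange(samples_per_side) + 0.5) / samples_per_side
    fracs = {}
    for r in range(r0, r1):
        for c in range(c0, c1):
            xs = t.x0 + (c + offs) * t.dx
            ys = t.y0 + (r + offs) * t.dy
            xx, yy = np.meshgrid(xs, ys)
            inside = shapely.contains_xy(polygon, xx.ravel(), yy.ravel())
            f = inside.mean()
            if f > 0:
                fracs[(r, c)] = f
    return fracs
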