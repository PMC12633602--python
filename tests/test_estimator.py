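"""The four exposure modes, unions, component grouping, denominators, and
determinism."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from nearpop import (
    GeoTable,
    PopEstimator,
    est_exposed_pop,
    est_total_pop,
    group_components,
    make_admin_tiling,
    make_rect_hazards,
    union_per_column,
    write_geo,
    write_raster,
)
from nearpop.projection import buffer_hazards


def buffered_from_rects(spec, rects, ids=None):
    """Grid-aligned buffered table (buffer 0 keeps the polygons exact)."""
    haz = make_rect_hazards(spec, rects, ids=ids, buffer=0.0)
    return buffer_hazards(haz, out_crs=spec.crs)


# --- est_exposed_pop modes --------------------------------------------------

def test_identical_hazards_double_count_in_mode_a_but_not_b(metric_spec, uniform_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (0, 10, 0, 10)])
    res_a = est_exposed_pop(buffered, True, uniform_raster)
    assert res_a["exposed_main"].tolist() == pytest.approx([100.0, 100.0])
    res_b = est_exposed_pop(buffered, False, uniform_raster)
    assert len(res_b) == 1
    assert res_b["exposed_main"][0] == pytest.approx(100.0)


def test_disjoint_hazards_cumulative_equals_sum(metric_spec, uniform_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (10, 20, 10, 20)])
    res_a = est_exposed_pop(buffered, True, uniform_raster)
    res_b = est_exposed_pop(buffered, False, uniform_raster)
    assert res_b["exposed_main"][0] == pytest.approx(res_a["exposed_main"].sum())
    assert res_b["exposed_main"][0] == pytest.approx(200.0)


def test_half_overlapping_squares_inclusion_exclusion(metric_spec, uniform_raster):
    # two 10x10 squares overlapping in 50 cells: a -> {100, 100}, b -> 150
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (0, 10, 5, 15)])
    res_a = est_exposed_pop(buffered, True, uniform_raster)
    assert res_a["exposed_main"].tolist() == pytest.approx([100.0, 100.0])
    res_b = est_exposed_pop(buffered, False, uniform_raster)
    assert res_b["exposed_main"][0] == pytest.approx(150.0)


def test_admin_decomposition_conserves_totals(metric_spec, uniform_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (0, 10, 5, 15)])
    admin = make_admin_tiling(metric_spec, 2, 2)
    res_d = est_exposed_pop(buffered, False, uniform_raster, admin=admin)
    assert len(res_d) == 4
    res_b = est_exposed_pop(buffered, False, uniform_raster)
    assert res_d["exposed_main"].sum() == pytest.approx(
        res_b["exposed_main"][0], rel=1e-6
    )
    # mode c rows sum to the mode a value per hazard
    res_c = est_exposed_pop(buffered, True, uniform_raster, admin=admin, all_pairs=True)
    res_a = est_exposed_pop(buffered, True, uniform_raster)
    per_hazard = res_c.groupby("ID_hazard")["exposed_main"].sum()
    for hid, val in zip(res_a["ID_hazard"], res_a["exposed_main"]):
        assert per_hazard[hid] == pytest.approx(val, rel=1e-6)


def test_mode_c_emits_pairs_with_zero_rows_and_all_pairs_flag(metric_spec, uniform_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 5, 0, 5)], ids=["h"])
    admin = make_admin_tiling(metric_spec, 2, 2)
    res = est_exposed_pop(buffered, True, uniform_raster, admin=admin)
    # bbox prefilter keeps only candidate pairs; the hazard sits in one tile
    assert set(res.columns) == {"ID_hazard", "ID_admin_unit", "exposed_main"}
    assert len(res) <= 4
    res_all = est_exposed_pop(buffered, True, uniform_raster, admin=admin, all_pairs=True)
    assert len(res_all) == 4
    assert res_all["exposed_main"].sum() == pytest.approx(25.0)
    zero_rows = res_all[res_all["ID_admin_unit"] != "admin_0_0"]
    assert (zero_rows["exposed_main"] == 0).all()


def test_hazard_outside_raster_keeps_row_with_zero(metric_spec, uniform_raster):
    t = metric_spec.transform
    df = pd.DataFrame({"ID_hazard": ["far"]})
    df["buffered_hazard_main"] = [box(t.x0 - 50_000, t.y0, t.x0 - 49_000, t.y0 + 1_000)]
    df["geometry"] = df["buffered_hazard_main"]
    buffered = GeoTable(df, metric_spec.crs, geometry_column="buffered_hazard_main")
    res = est_exposed_pop(buffered, True, uniform_raster)
    assert res["ID_hazard"].tolist() == ["far"]
    assert res["exposed_main"][0] == 0.0


def test_multiple_buffer_columns_are_independent_and_monotone(metric_spec, uniform_raster):
    df = pd.DataFrame({"ID_hazard": ["h1", "h2"]})
    df["buffered_hazard_small"] = [
        metric_spec.cell_box(0, 5, 0, 5),
        metric_spec.cell_box(10, 12, 10, 12),
    ]
    df["buffered_hazard_big"] = [
        metric_spec.cell_box(0, 8, 0, 8),
        metric_spec.cell_box(9, 14, 9, 14),
    ]
    buffered = GeoTable(df, metric_spec.crs, geometry_column="buffered_hazard_small")
    res = est_exposed_pop(buffered, True, uniform_raster)
    assert (res["exposed_big"] >= res["exposed_small"]).all()
    assert res["exposed_small"].tolist() == pytest.approx([25.0, 4.0])
    assert res["exposed_big"].tolist() == pytest.approx([64.0, 25.0])


def test_cumulative_never_exceeds_sum_of_hazard_specific(metric_spec, random_raster):
    buffered = buffered_from_rects(
        metric_spec, [(0, 10, 0, 10), (5, 15, 5, 15), (16, 20, 16, 20)]
    )
    res_a = est_exposed_pop(buffered, True, random_raster)
    res_b = est_exposed_pop(buffered, False, random_raster)
    assert res_b["exposed_main"][0] <= res_a["exposed_main"].sum() + 1e-9
    # strict inequality since two of the squares overlap
    assert res_b["exposed_main"][0] < res_a["exposed_main"].sum()


# --- union / grouping -------------------------------------------------------

def test_union_per_column(metric_spec):
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (12, 20, 12, 20)])
    merged = union_per_column(buffered, "main")
    assert merged.geom_type == "MultiPolygon"
    assert len(merged.geoms) == 2
    assert merged.area == pytest.approx((100 + 64) * (100.0 * 100.0))

    overlapping = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (0, 10, 5, 15)])
    assert union_per_column(overlapping, "main").area == pytest.approx(
        150 * 100.0 * 100.0
    )

    single = buffered_from_rects(metric_spec, [(0, 10, 0, 10)])
    assert union_per_column(single, "main").equals(metric_spec.cell_box(0, 10, 0, 10))


def test_group_components_pairwise_and_transitive():
    a = box(0, 0, 2, 2)
    b = box(1, 1, 3, 3)
    c = box(10, 10, 11, 11)
    groups = {frozenset(g) for g in group_components([a, b, c])}
    assert groups == {frozenset({0, 1}), frozenset({2})}

    # chain: a-b intersect, b-c2 intersect, a-c2 do not -> one component
    c2 = box(2.5, 2.5, 4, 4)
    assert not a.intersects(c2)
    groups = group_components([a, b, c2])
    assert len(groups) == 1 and sorted(groups[0]) == [0, 1, 2]

    disjoint = [box(i * 10, 0, i * 10 + 1, 1) for i in range(4)]
    assert sorted(len(g) for g in group_components(disjoint)) == [1, 1, 1, 1]


# --- est_total_pop ----------------------------------------------------------

def test_total_pop_whole_extent_and_tiling(metric_spec, random_spec, random_raster):
    one = make_admin_tiling(random_spec, 1, 1)
    total = est_total_pop(one, random_raster)
    assert total["population"][0] == pytest.approx(
        random_raster.total_population(), rel=1e-9
    )
    four = make_admin_tiling(random_spec, 2, 2)
    res = est_total_pop(four, random_raster)
    assert len(res) == 4
    assert res["population"].sum() == pytest.approx(
        random_raster.total_population(), rel=1e-6
    )


def test_total_pop_half_cells_ramp(tmp_path):
    # 2-column ramp raster (value = row index); a unit covering the left
    # column contributes the full left cells only
    from nearpop import FixtureSpec, make_raster

    spec = FixtureSpec(grid_shape=(3, 2), cell_size=100.0, fill=("ramp",))
    with make_raster(spec, tmp_path / "ramp.tif") as raster:
        left = spec.cell_box(0, 3, 0, 1)
        df = pd.DataFrame({"ID_admin_unit": ["left"]})
        df["geometry"] = [left]
        res = est_total_pop(GeoTable(df, spec.crs), raster)
        assert res["population"][0] == pytest.approx(0.0 + 1.0 + 2.0)


def test_total_pop_empty_marker(random_raster):
    assert est_total_pop(None, random_raster) is None


def test_denominator_bounds_mode_d_exposure(metric_spec, random_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 15, 0, 15)])
    admin = make_admin_tiling(metric_spec, 2, 2)
    res_d = est_exposed_pop(buffered, False, random_raster, admin=admin)
    denom = est_total_pop(admin, random_raster).set_index("ID_admin_unit")
    for _, row in res_d.iterrows():
        assert row["exposed_main"] <= denom.loc[row["ID_admin_unit"], "population"] + 1e-9


# --- determinism & facade ---------------------------------------------------

def test_estimates_are_bit_identical_across_runs(metric_spec, random_raster):
    buffered = buffered_from_rects(metric_spec, [(0, 10, 0, 10), (3, 17, 2, 12)])
    admin = make_admin_tiling(metric_spec, 2, 2)
    r1 = est_exposed_pop(buffered, True, random_raster, admin=admin)
    r2 = est_exposed_pop(buffered, True, random_raster, admin=admin)
    pd.testing.assert_frame_equal(r1, r2)
    assert (r1["exposed_main"].to_numpy() == r2["exposed_main"].to_numpy()).all()
    t1 = est_total_pop(admin, random_raster)
    t2 = est_total_pop(admin, random_raster)
    assert (t1["population"].to_numpy() == t2["population"].to_numpy()).all()


def test_pop_estimator_facade_runs_files_end_to_end(tmp_path, metric_spec):
    from nearpop import make_raster

    raster_path = tmp_path / "pop.tif"
    make_raster(metric_spec, raster_path).close()
    hazards = make_rect_hazards(metric_spec, [(0, 10, 0, 10)], buffer=500.0)
    write_geo(hazards, tmp_path / "haz.parquet")
    admin = make_admin_tiling(metric_spec, 2, 2)
    write_geo(admin, tmp_path / "admin.parquet")

    est = PopEstimator(pop_path=str(raster_path), admin_path=str(tmp_path / "admin.parquet"))
    buffered = est.prep_data(str(tmp_path / "haz.parquet"))
    assert buffered is not None and "buffered_hazard_main" in buffered.df.columns
    res = est.est_exposed_pop(buffered, hazard_specific=False)
    assert set(res.columns) == {"ID_admin_unit", "exposed_main"}
    totals = est.est_total_pop()
    assert totals["population"].sum() == pytest.approx(400.0, rel=1e-9)
    # buffered exposure exceeds the unbuffered square's 100 people
    assert res["exposed_main"].sum() > 100.0
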