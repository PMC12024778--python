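"""HPP scoring: hand values, monotonicity, additivity, rasterisation."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, box

from melliflow.flora import (
    PhenologyCalendar,
    assign_observations,
    cover_table,
)
from melliflow.hpp import (
    compute_surface,
    distance_factor,
    luu_weekly_hpp,
    lus_share_of_taxon,
    rank_taxa,
    rasterize,
)
from melliflow.landscape import LUU, Landscape


def _luu_at(dist_m: float, area_ha: float, lus="grassland", luu_id="u"):
    """A square patch whose centroid is dist_m east of the origin."""
    side = np.sqrt(area_ha * 10_000)
    return LUU(
        luu_id, lus, box(dist_m - side / 2, -side / 2, dist_m + side / 2, side / 2)
    )


FULL_W20 = {"x": PhenologyCalendar("x", {20: "full"}), "y": PhenologyCalendar("y", {20: "full"})}


def test_hand_evaluation():
    # decay 0.85, S = 2 ha, terms 0.5*8 + 0.2*30 -> 17 kg
    luu = _luu_at(1500.0, 2.0)
    hpp = luu_weekly_hpp(
        luu,
        Point(0, 0),
        {"x": 50.0, "y": 20.0},
        {"x": 8.0, "y": 30.0},
        FULL_W20,
        week=20,
    )
    assert hpp == pytest.approx(17.0, rel=1e-12)


def test_identity_substitution_at_apiary():
    luu = _luu_at(0.0, 1.0)
    hpp = luu_weekly_hpp(
        luu, Point(0, 0), {"x": 100.0}, {"x": 10.0},
        {"x": PhenologyCalendar("x", {20: "full"})}, week=20,
    )
    assert hpp == pytest.approx(10.0)


def test_distance_factor_clamps_to_zero():
    assert distance_factor(10_000.0) == 0.0
    assert distance_factor(25_000.0) == 0.0
    with pytest.raises(ValueError):
        distance_factor(-1.0)
    luu = _luu_at(10_000.0, 5.0)
    hpp = luu_weekly_hpp(
        luu, Point(0, 0), {"x": 100.0}, {"x": 500.0},
        {"x": PhenologyCalendar("x", {20: "full"})}, week=20,
    )
    assert hpp == 0.0


def test_hpp_non_increasing_in_distance():
    vals = []
    for d in np.linspace(0, 10_000, 21):
        luu = _luu_at(d, 1.0)
        vals.append(
            luu_weekly_hpp(
                luu, Point(0, 0), {"x": 50.0}, {"x": 10.0},
                {"x": PhenologyCalendar("x", {20: "full"})}, week=20,
            )
        )
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] == 0.0 and min(vals) >= 0.0


def test_hpp_linear_in_area_and_cover():
    base = luu_weekly_hpp(
        _luu_at(2000, 1.0), Point(0, 0), {"x": 25.0}, {"x": 10.0}, FULL_W20, 20
    )
    double_area = luu_weekly_hpp(
        _luu_at(2000, 2.0), Point(0, 0), {"x": 25.0}, {"x": 10.0}, FULL_W20, 20
    )
    double_cover = luu_weekly_hpp(
        _luu_at(2000, 1.0), Point(0, 0), {"x": 50.0}, {"x": 10.0}, FULL_W20, 20
    )
    assert double_area == pytest.approx(2 * base, rel=1e-12)
    assert double_cover == pytest.approx(2 * base, rel=1e-12)


def test_negative_cover_fails():
    with pytest.raises(ValueError, match="cover"):
        luu_weekly_hpp(
            _luu_at(0, 1.0), Point(0, 0), {"x": -5.0}, {"x": 10.0}, FULL_W20, 20
        )


def test_taxa_without_pnt_are_skipped():
    hpp = luu_weekly_hpp(
        _luu_at(0, 1.0), Point(0, 0), {"x": 100.0, "z": 100.0},
        {"x": 10.0, "z": float("nan")},
        {"x": PhenologyCalendar("x", {20: "full"}),
         "z": PhenologyCalendar("z", {20: "full"})},
        week=20,
    )
    assert hpp == pytest.approx(10.0)


def _small_surface():
    luus = [
        LUU("a", "forest", box(0, 0, 100, 100)),
        LUU("b", "grassland", box(200, 0, 300, 100)),
        LUU("c", "grassland", box(0, 200, 100, 300)),
    ]
    land = Landscape(luus, apiary=Point(50, 50))
    cover = pd.DataFrame(
        [("a", "t1", 40.0), ("b", "t1", 10.0), ("b", "t2", 60.0)],
        columns=["luu_id", "taxon", "rt_pct"],
    )
    traits = pd.DataFrame(
        [("t1", 100.0, "species-level"), ("t2", 50.0, "species-level")],
        columns=["taxon", "pnt_kg_ha", "provenance"],
    )
    calendars = {
        "t1": PhenologyCalendar("t1", {20: "early", 21: "full", 22: "late"}),
        "t2": PhenologyCalendar("t2", {23: "full"}),
    }
    return land, compute_surface(land, cover, traits, calendars)


def test_surface_temporal_support():
    _, surface = _small_surface()
    weekly = surface.total_by_week()
    nonzero = {int(w) for w, v in weekly.items() if v > 0}
    assert nonzero == {20, 21, 22, 23}


def test_surface_additivity_closure():
    _, surface = _small_surface()
    per_week_luu = surface.luu_week.groupby("week")["hpp_kg"].sum()
    per_week_lus = surface.per_lus.groupby("week")["hpp_kg"].sum()
    pd.testing.assert_series_equal(
        per_week_luu, per_week_lus, check_exact=False, rtol=1e-12
    )
    assert surface.per_taxon["hpp_kg"].sum() == pytest.approx(
        surface.total(), rel=1e-12
    )


def test_surface_all_empty_assignments_is_zero():
    luus = [LUU("a", "forest", box(0, 0, 100, 100))]
    land = Landscape(luus, apiary=Point(0, 0))
    surface = compute_surface(
        land,
        pd.DataFrame(columns=["luu_id", "taxon", "rt_pct"]),
        pd.DataFrame(columns=["taxon", "pnt_kg_ha", "provenance"]),
        {},
    )
    assert surface.total() == 0.0
    assert set(surface.luu_week["luu_id"]) == {"a"}  # still total over LUUs


def test_rank_taxa_order_and_overflow():
    _, surface = _small_surface()
    full = rank_taxa(surface, 10)
    assert len(full) == 2
    manual = sorted(
        surface.per_taxon.itertuples(index=False),
        key=lambda r: (-r.hpp_kg, r.taxon),
    )
    assert list(full["taxon"]) == [r.taxon for r in manual]
    assert list(rank_taxa(surface, 1)["taxon"]) == [manual[0].taxon]
    with pytest.raises(ValueError):
        rank_taxa(surface, 0)


def test_lus_share_of_taxon_sums_to_100():
    _, surface = _small_surface()
    shares = lus_share_of_taxon(surface, "t1")
    assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)
    assert set(shares) == {"forest", "grassland"}
    only_grass = lus_share_of_taxon(surface, "t2")
    assert only_grass == {"grassland": pytest.approx(100.0)}
    with pytest.raises(ValueError, match="no HPP"):
        lus_share_of_taxon(surface, "missing")


def test_rasterize_uniform_patch_and_oracle():
    land, surface = _small_surface()
    grid, (xmin, ymin, cell) = rasterize(surface, land, week=21, cell_size=10.0)
    # all cells centred inside patch "a" share its weekly value
    val_a = surface.value("a", 21)
    assert val_a > 0
    # oracle: point-in-polygon on random cells
    rng = np.random.default_rng(5)
    nrow, ncol = grid.shape
    geoms = {u.luu_id: u.polygon for u in land.luus}
    wk = surface.luu_week[surface.luu_week["week"] == 21]
    by_luu = dict(zip(wk["luu_id"], wk["hpp_kg"]))
    for _ in range(1000):
        i = int(rng.integers(nrow))
        j = int(rng.integers(ncol))
        x = xmin + (j + 0.5) * cell
        y = ymin + (nrow - 1 - i + 0.5) * cell
        p = Point(x, y)
        inside = [lid for lid, g in geoms.items() if g.intersects(p)]
        if inside:
            assert grid[i, j] == pytest.approx(by_luu[inside[0]])
        else:
            assert np.isnan(grid[i, j])


def test_rasterize_zero_week_and_bad_cell():
    land, surface = _small_surface()
    grid, _ = rasterize(surface, land, week=10, cell_size=25.0)
    vals = grid[~np.isnan(grid)]
    assert len(vals) and (vals == 0.0).all()
    with pytest.raises(ValueError):
        rasterize(surface, land, week=10, cell_size=0.0)


def test_default_surface_additivity(default_landscape, default_survey):
    plots, traits, calendars = default_survey
    cover = cover_table(assign_observations(default_landscape, plots))
    surface = compute_surface(default_landscape, cover, traits, calendars)
    total = surface.total()
    assert total > 0
    assert surface.per_lus["hpp_kg"].sum() == pytest.approx(total, rel=1e-9)
    assert surface.per_taxon["hpp_kg"].sum() == pytest.approx(total, rel=1e-9)
    assert (surface.luu_week["hpp_kg"] >= 0).all()
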