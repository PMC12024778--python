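"""Cover conversion, phenology weighting, plot assignment, richness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st_
from shapely.geometry import Point, box

from melliflow.flora import (
    BRAUN_BLANQUET_COVER,
    ObservationPlot,
    PhenologyCalendar,
    WEEKS,
    assign_observations,
    cover_rate,
    cover_table,
    flowering_intensity,
    group_plots_by_lus,
    richness_summary,
    weekly_nectar_potential,
    weekly_potential_series,
)
from melliflow.landscape import LUU, Landscape


@pytest.mark.parametrize(
    "bb,pct",
    [("r", 0.1), ("+", 0.5), ("1", 2.5), ("2", 15.0), ("3", 37.5), ("4", 62.5), ("5", 87.5)],
)
def test_cover_rate_midpoints(bb, pct):
    assert cover_rate(bb) == pct


def test_cover_rate_strictly_increasing():
    order = ["r", "+", "1", "2", "3", "4", "5"]
    vals = [cover_rate(c) for c in order]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_cover_rate_unknown_class_fails():
    with pytest.raises(ValueError, match="Braun-Blanquet"):
        cover_rate("6")


@pytest.mark.parametrize(
    "phase,intensity", [("none", 0.0), ("early", 0.5), ("full", 1.0), ("late", 0.5)]
)
def test_flowering_intensity_mapping(phase, intensity):
    cal = PhenologyCalendar("t", {20: phase} if phase != "none" else {})
    assert flowering_intensity(cal, 20) == intensity
    assert flowering_intensity(cal, 34) == 0.0  # outside the window


def test_weekly_potential_direct_substitution():
    cal = PhenologyCalendar("t", {20: "early", 21: "full", 22: "full", 23: "late"})
    assert cal.sf == 4
    assert weekly_nectar_potential(100.0, cal, 21) == pytest.approx(25.0)
    assert weekly_nectar_potential(100.0, cal, 20) == pytest.approx(12.5)
    assert weekly_nectar_potential(100.0, cal, 10) == 0.0
    series = weekly_potential_series(100.0, cal)
    assert list(series.loc[[20, 21, 22, 23]]) == [12.5, 25.0, 25.0, 12.5]
    assert series.sum() == pytest.approx(75.0)


def test_empty_calendar_with_positive_pnt_fails():
    cal = PhenologyCalendar("t", {})
    with pytest.raises(ValueError, match="Sf = 0"):
        weekly_nectar_potential(10.0, cal, 20)
    assert weekly_nectar_potential(0.0, cal, 20) == 0.0


@given(
    phases=st_.dictionaries(
        st_.integers(min_value=10, max_value=34),
        st_.sampled_from(["early", "full", "late"]),
        min_size=1,
        max_size=25,
    ),
    pnt=st_.floats(min_value=0.01, max_value=1e4),
)
def test_annual_potential_conservation(phases, pnt):
    """Sum of weekly potentials never exceeds pnt; equality iff all-full."""
    cal = PhenologyCalendar("t", phases)
    total = sum(weekly_nectar_potential(pnt, cal, w) for w in WEEKS)
    assert total <= pnt * (1 + 1e-12)
    all_full = all(p == "full" for p in phases.values())
    if all_full:
        assert total == pytest.approx(pnt, rel=1e-12)
    else:
        assert total < pnt


def _toy_world():
    luus = [
        LUU("own", "grassland", box(0, 0, 100, 100)),
        LUU("empty_grass", "grassland", box(0, 200, 100, 300)),
        LUU("forest1", "forest", box(0, 120, 100, 180)),
        LUU("hab", "habitation", box(200, 0, 300, 100)),
    ]
    land = Landscape(luus, apiary=Point(50, 50))
    plots = [
        ObservationPlot("p1", 10, 10, "herb", "own", (("A", "2"), ("B", "5"))),
        ObservationPlot("p2", 90, 90, "herb", "own", (("B", "1"),)),
        # forest plot much closer to the empty grassland patch than p1/p2
        ObservationPlot("p3", 50, 150, "tree", "forest1", (("C", "3"),)),
    ]
    return land, plots


def test_assignment_own_plots_kept():
    land, plots = _toy_world()
    a = assign_observations(land, plots)
    assert {p.plot_id for p in a["own"]} == {"p1", "p2"}


def test_assignment_same_lus_fallback_beats_closer_other_lus():
    land, plots = _toy_world()
    a = assign_observations(land, plots)
    # empty grassland centroid (50, 250): forest plot is 100 m away,
    # grassland plots ~250 m away -> same-LUS rule still picks grassland
    assert [p.plot_id for p in a["empty_grass"]] == ["p2"]
    b = assign_observations(land, plots, same_lus_only=False)
    assert [p.plot_id for p in b["empty_grass"]] == ["p3"]


def test_assignment_unsurveyed_lus_stays_empty_and_total():
    land, plots = _toy_world()
    a = assign_observations(land, plots)
    assert a["hab"] == []
    assert set(a) == {u.luu_id for u in land.luus}  # total over LUUs
    kept = {p.plot_id for ps in a.values() for p in ps}
    assert {"p1", "p2", "p3"} <= kept  # no plot lost


def test_cover_table_mean_with_absence_as_zero():
    land, plots = _toy_world()
    a = assign_observations(land, plots)
    table = cover_table(a)
    own = table[table["luu_id"] == "own"].set_index("taxon")["rt_pct"]
    assert own["A"] == pytest.approx(15.0 / 2)  # present on 1 of 2 plots
    assert own["B"] == pytest.approx((87.5 + 2.5) / 2)


def test_richness_summary_hand_case():
    plots = [
        ObservationPlot("p1", 0, 0, "herb", "u1", (("A", "1"), ("B", "1"))),
        ObservationPlot("p2", 1, 1, "herb", "u1", (("B", "1"), ("C", "1"))),
    ]
    out = richness_summary({"grassland": plots})
    row = out.iloc[0]
    assert row["total_species"] == 3
    assert row["mean_per_plot"] == pytest.approx(2.0)


def test_richness_single_plot():
    plots = [
        ObservationPlot(
            "p1", 0, 0, "herb", "u1",
            tuple((t, "1") for t in "ABCDE"),
        )
    ]
    out = richness_summary({"forest": plots})
    assert out.iloc[0]["total_species"] == 5
    assert out.iloc[0]["mean_per_plot"] == pytest.approx(5.0)
    assert out.iloc[0]["sd_per_plot"] == 0.0


def test_group_plots_by_lus(default_landscape, default_survey):
    plots, _, _ = default_survey
    grouped = group_plots_by_lus(default_landscape, plots)
    assert sum(len(v) for v in grouped.values()) == len(plots)
    assert set(grouped) <= set(default_landscape.lus_present())
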