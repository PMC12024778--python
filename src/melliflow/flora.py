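"""Melliferous flora: survey plots, cover rates, traits, phenology.

Vegetation is surveyed on circular plots whose radius depends on the
stratum (herb 0.56 m, shrub 4 m, tree 8 m). Each taxon on a plot receives
a Braun-Blanquet abundance-dominance class, converted here to a percent
cover via the conventional class midpoints. Flowering is tracked weekly
over weeks 10-34 as one of three phenophases (early / full / late), which
weight the taxon's annual nectariferous potential into a weekly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .landscape import LUU, Landscape, UNSURVEYED_LUS

#: Survey weeks (ISO weeks 10-34, March through August).
WEEKS: tuple[int, ...] = tuple(range(10, 35))

#: Plot radius (m) per vegetation stratum.
STRATUM_RADIUS: dict[str, float] = {"herb": 0.56, "shrub": 4.0, "tree": 8.0}

#: Braun-Blanquet class -> percent cover (band midpoints; r and + are the
#: conventional token values for solitary / sparse individuals).
BRAUN_BLANQUET_COVER: dict[str, float] = {
    "r": 0.1,
    "+": 0.5,
    "1": 2.5,
    "2": 15.0,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}

#: Phenophase -> flowering intensity If.
PHASE_INTENSITY: dict[str, float] = {
    "none": 0.0,
    "early": 0.5,
    "full": 1.0,
    "late": 0.5,
}

PHASES: tuple[str, ...] = ("none", "early", "full", "late")


def cover_rate(bb_class: str) -> float:
    """Percent cover for a Braun-Blanquet abundance-dominance class."""
    try:
        return BRAUN_BLANQUET_COVER[str(bb_class)]
    except KeyError:
        raise ValueError(f"unknown Braun-Blanquet class {bb_class!r}") from None


@dataclass(frozen=True)
class ObservationPlot:
    """A circular botanical survey plot inside one LUU.

    ``records`` lists the (taxon, Braun-Blanquet class) pairs observed on
    the plot; grasses are never recorded.
    """

    plot_id: str
    x: float
    y: float
    stratum: str
    luu_id: str
    records: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.stratum not in STRATUM_RADIUS:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        for _, bb in self.records:
            cover_rate(bb)  # validates

    @property
    def radius_m(self) -> float:
        return STRATUM_RADIUS[self.stratum]

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.records)


@dataclass(frozen=True)
class PhenologyCalendar:
    """Weekly flowering phenophases for one taxon over weeks 10-34.

    Weeks absent from ``phase_by_week`` (and any week outside 10-34) are
    treated as not flowering.
    """

    taxon: str
    phase_by_week: Mapping[int, str]

    def __post_init__(self) -> None:
        for w, p in self.phase_by_week.items():
            if p not in PHASES:
                raise ValueError(f"unknown phenophase {p!r} for {self.taxon!r}")
            if w not in WEEKS and p != "none":
                raise ValueError(
                    f"flowering week {w} outside weeks {WEEKS[0]}-{WEEKS[-1]}"
                )

    def phase(self, week: int) -> str:
        return self.phase_by_week.get(week, "none")

    @property
    def flowering_weeks(self) -> tuple[int, ...]:
        return tuple(w for w in WEEKS if self.phase(w) != "none")

    @property
    def sf(self) -> int:
        """Flowering duration Sf: the number of weeks with phase != none."""
        return len(self.flowering_weeks)


def flowering_intensity(calendar: PhenologyCalendar, week: int) -> float:
    """Flowering intensity If: 1 at full flowering, 0.5 early/late, else 0."""
    return PHASE_INTENSITY[calendar.phase(week)]


def weekly_nectar_potential(
    pnt: float, calendar: PhenologyCalendar, week: int
) -> float:
    """Weekly nectariferous potential pnht (kg/ha/week) of one taxon.

    The annual potential ``pnt`` is spread uniformly over the Sf flowering
    weeks and weighted by the week's flowering intensity:
    ``pnht = pnt / Sf * If(week)``.
    """
    if pnt < 0:
        raise ValueError("pnt must be non-negative")
    sf = calendar.sf
    if sf == 0:
        if pnt > 0:
            raise ValueError(
                f"taxon {calendar.taxon!r} has pnt > 0 but an empty flowering "
                "calendar (Sf = 0)"
            )
        return 0.0
    return pnt / sf * flowering_intensity(calendar, week)


def weekly_potential_series(pnt: float, calendar: PhenologyCalendar) -> pd.Series:
    """pnht over all weeks 10-34, indexed by week."""
    return pd.Series(
        [weekly_nectar_potential(pnt, calendar, w) for w in WEEKS],
        index=pd.Index(WEEKS, name="week"),
        name=calendar.taxon,
    )


# ---------------------------------------------------------------------------
# Observation-to-LUU assignment and LUU-level cover
# ---------------------------------------------------------------------------


def assign_observations(
    landscape: Landscape,
    plots: Sequence[ObservationPlot],
    same_lus_only: bool = True,
) -> dict[str, list[ObservationPlot]]:
    """Assign survey plots to every LUU of the landscape.

    An LUU containing one or more plots uses exactly those plots. A
    plot-less LUU borrows the nearest plot (LUU centroid to plot
    distance). With ``same_lus_only`` (default) the borrowed plot must sit
    on an LUU of the same LUS, so community composition stays coherent
    across the land-use class; if that LUS has no plots anywhere, the LUU
    gets an empty set. With ``same_lus_only=False`` the globally nearest
    plot is borrowed regardless of land use.

    The mapping is total: every LUU id appears, possibly with an empty
    list, and every plot is kept by its own LUU.
    """
    if not plots:
        return {u.luu_id: [] for u in landscape.luus}
    own: dict[str, list[ObservationPlot]] = {u.luu_id: [] for u in landscape.luus}
    lus_by_luu = {u.luu_id: u.lus for u in landscape.luus}
    for p in plots:
        if p.luu_id not in own:
            raise KeyError(f"plot {p.plot_id!r} references unknown LUU {p.luu_id!r}")
        own[p.luu_id].append(p)

    out: dict[str, list[ObservationPlot]] = {}
    for u in landscape.luus:
        if own[u.luu_id]:
            out[u.luu_id] = list(own[u.luu_id])
            continue
        if same_lus_only:
            candidates = [p for p in plots if lus_by_luu[p.luu_id] == u.lus]
        else:
            candidates = list(plots)
        if not candidates:
            out[u.luu_id] = []
            continue
        c = u.centroid
        # deterministic tie-break on plot_id
        best = min(candidates, key=lambda p: (c.distance(p.location), p.plot_id))
        out[u.luu_id] = [best]
    return out


def cover_table(
    assignments: Mapping[str, Sequence[ObservationPlot]],
) -> pd.DataFrame:
    """Per-LUU taxon cover rates Rt (%) from assigned plots.

    For an LUU with several plots, a taxon's Rt is the mean of its cover
    over all that LUU's plots, counting absence on a plot as 0%. Duplicate
    records of a taxon on one plot (e.g. in two strata) keep the highest
    class before averaging.

    Returns a long DataFrame with columns ``luu_id, taxon, rt_pct``.
    """
    rows: list[tuple[str, str, float]] = []
    for luu_id, pls in assignments.items():
        if not pls:
            continue
        n = len(pls)
        acc: dict[str, float] = {}
        for p in pls:
            per_plot: dict[str, float] = {}
            for taxon, bb in p.records:
                c = cover_rate(bb)
                per_plot[taxon] = max(per_plot.get(taxon, 0.0), c)
            for taxon, c in per_plot.items():
                acc[taxon] = acc.get(taxon, 0.0) + c
        for taxon in sorted(acc):
            rows.append((luu_id, taxon, acc[taxon] / n))
    return pd.DataFrame(rows, columns=["luu_id", "taxon", "rt_pct"])


# ---------------------------------------------------------------------------
# Richness summaries
# ---------------------------------------------------------------------------


def group_plots_by_lus(
    landscape: Landscape, plots: Sequence[ObservationPlot]
) -> dict[str, list[ObservationPlot]]:
    lus_by_luu = {u.luu_id: u.lus for u in landscape.luus}
    out: dict[str, list[ObservationPlot]] = {}
    for p in plots:
        out.setdefault(lus_by_luu[p.luu_id], []).append(p)
    return out


def richness_summary(
    plots_by_lus: Mapping[str, Sequence[ObservationPlot]],
) -> pd.DataFrame:
    """Total and per-plot plant richness by land-use station.

    ``total_species`` is the cardinality of the union of taxa over the
    LUS's plots; ``mean_per_plot`` / ``sd_per_plot`` summarise the
    per-plot record counts (sample SD; 0 for a single plot).
    """
    rows = []
    for lus, pls in plots_by_lus.items():
        if not pls:
            continue
        union: set[str] = set()
        counts = []
        for p in pls:
            taxa = set(p.taxa)
            union |= taxa
            counts.append(len(taxa))
        arr = np.asarray(counts, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append((lus, len(union), float(arr.mean()), sd, len(pls)))
    return pd.DataFrame(
        rows, columns=["lus", "total_species", "mean_per_plot", "sd_per_plot", "n_plots"]
    ).sort_values("lus", ignore_index=True)


# ---------------------------------------------------------------------------
# Tabular I/O (CSV schemas shared with the synthetic generator)
# ---------------------------------------------------------------------------


def plots_to_frames(
    plots: Sequence[ObservationPlot],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split plots into a plot table and a long record table."""
    prows = [(p.plot_id, p.x, p.y, p.luu_id, p.stratum) for p in plots]
    rrows = [(p.plot_id, t, bb) for p in plots for t, bb in p.records]
    return (
        pd.DataFrame(prows, columns=["plot_id", "x", "y", "luu_id", "stratum"]),
        pd.DataFrame(rrows, columns=["plot_id", "taxon", "bb_class"]),
    )


def plots_from_frames(
    plot_df: pd.DataFrame, record_df: pd.DataFrame
) -> list[ObservationPlot]:
    recs: dict[str, list[tuple[str, str]]] = {}
    for r in record_df.itertuples(index=False):
        recs.setdefault(str(r.plot_id), []).append((str(r.taxon), str(r.bb_class)))
    out = []
    for r in plot_df.itertuples(index=False):
        pid = str(r.plot_id)
        out.append(
            ObservationPlot(
                pid, float(r.x), float(r.y), str(r.stratum), str(r.luu_id),
                tuple(recs.get(pid, [])),
            )
        )
    return out


def calendars_to_frame(calendars: Mapping[str, PhenologyCalendar]) -> pd.DataFrame:
    rows = [
        (cal.taxon, w, cal.phase(w))
        for cal in calendars.values()
        for w in WEEKS
        if cal.phase(w) != "none"
    ]
    return pd.DataFrame(rows, columns=["taxon", "week", "phase"])


def calendars_from_frame(df: pd.DataFrame) -> dict[str, PhenologyCalendar]:
    out: dict[str, PhenologyCalendar] = {}
    for taxon, grp in df.groupby("taxon", sort=True):
        out[str(taxon)] = PhenologyCalendar(
            str(taxon), {int(r.week): str(r.phase) for r in grp.itertuples(index=False)}
        )
    return out
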