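"""Honey production potential (HPP) scoring and aggregation.

Per patch (LUU) and week, HPP combines a linear distance decay to the
apiary, the patch area, and the cover-weighted weekly nectariferous
potential of its taxa:

    HPP = max(0, 1 - D / 10,000) * S * sum_t (Rt / 100 * pnht_t)

with D the centroid-to-apiary distance (m), S the patch area (ha), Rt
the taxon's percent cover on the patch, and pnht_t = pnt_t / Sf_t * If_t
the taxon's weekly potential (kg/ha). The decay factor is clamped at 0
beyond 10 km, where the linear form would go negative; within a 1.5 km
foraging radius the clamp is inert. Taxa without a published potential
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .landscape import LUU, Landscape, M2_PER_HA
from .flora import (
    ObservationPlot,
    PhenologyCalendar,
    WEEKS,
    weekly_nectar_potential,
)

#: Distance (m) at which the linear decay factor reaches zero.
DECAY_RANGE_M = 10_000.0

#: Default seasonal period bins (week ranges, inclusive).
DEFAULT_PERIODS: dict[str, tuple[int, int]] = {
    "period_1": (10, 15),
    "period_2": (16, 19),
    "period_3": (20, 27),
    "period_4": (28, 34),
}


def distance_factor(d_m: float) -> float:
    if d_m < 0:
        raise ValueError("distance must be non-negative")
    return max(0.0, 1.0 - d_m / DECAY_RANGE_M)


def luu_weekly_hpp(
    luu: LUU,
    apiary: Point,
    cover: Mapping[str, float],
    pnt: Mapping[str, float],
    calendars: Mapping[str, PhenologyCalendar],
    week: int,
) -> float:
    """HPP (kg/week) of one patch for one week.

    ``cover`` maps taxon -> Rt percent cover on the patch; ``pnt`` maps
    taxon -> annual nectariferous potential (kg/ha). Taxa missing from
    ``pnt`` (or with NaN potential) do not contribute.
    """
    d = luu.centroid.distance(apiary)
    w = distance_factor(d)
    total = 0.0
    for taxon, rt in cover.items():
        if not 0.0 <= rt <= 100.0:
            raise ValueError(f"cover for {taxon!r} outside [0, 100]: {rt!r}")
        p = pnt.get(taxon)
        if p is None or np.isnan(p):
            continue
        total += rt / 100.0 * weekly_nectar_potential(p, calendars[taxon], week)
    return w * luu.area_ha * total


@dataclass
class WeeklyHPPSurface:
    """Per-LUU weekly HPP values with all bookkeeping aggregations.

    ``luu_week``: long frame (luu_id, lus, week, hpp_kg);
    ``per_lus``: (lus, week, hpp_kg, hpp_kg_per_ha) — per-area values
    divide by the station's *total* area (ha), contributing or not;
    ``per_taxon``: (taxon, hpp_kg) cumulative over all weeks;
    ``per_taxon_lus``: (taxon, lus, hpp_kg) cumulative split.
    """

    luu_week: pd.DataFrame
    per_lus: pd.DataFrame
    per_taxon: pd.DataFrame
    per_taxon_lus: pd.DataFrame
    weeks: tuple[int, ...] = WEEKS

    def total_by_week(self) -> pd.Series:
        s = self.luu_week.groupby("week")["hpp_kg"].sum()
        return s.reindex(list(self.weeks), fill_value=0.0)

    def total(self) -> float:
        return float(self.luu_week["hpp_kg"].sum())

    def value(self, luu_id: str, week: int) -> float:
        m = self.luu_week
        sel = m[(m["luu_id"] == luu_id) & (m["week"] == week)]["hpp_kg"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def period_totals(
        self, periods: Mapping[str, tuple[int, int]] = DEFAULT_PERIODS
    ) -> pd.DataFrame:
        """Total HPP per seasonal period and station."""
        rows = []
        for name, (w0, w1) in periods.items():
            sub = self.luu_week[self.luu_week["week"].between(w0, w1)]
            for lus, v in sub.groupby("lus")["hpp_kg"].sum().items():
                rows.append((name, w0, w1, lus, float(v)))
        return pd.DataFrame(
            rows, columns=["period", "week_start", "week_end", "lus", "hpp_kg"]
        )


def compute_surface(
    landscape: Landscape,
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    calendars: Mapping[str, PhenologyCalendar],
    weeks: Sequence[int] = WEEKS,
) -> WeeklyHPPSurface:
    """Score every (LUU, week) cell and build all aggregations.

    ``cover`` is the long per-LUU cover table (luu_id, taxon, rt_pct)
    from :func:`melliflow.flora.cover_table`; ``traits`` carries columns
    ``taxon, pnt_kg_ha``. The decompositions close exactly: summing the
    per-station or per-taxon tables reproduces the landscape total.
    """
    weeks = tuple(int(w) for w in weeks)
    pnt = dict(zip(traits["taxon"], traits["pnt_kg_ha"].astype(float)))

    luu_info = {
        u.luu_id: (u.lus, u.area_ha, distance_factor(u.centroid.distance(landscape.apiary)))
        for u in landscape.luus
    }

    # per-taxon weekly potential matrix (taxa x weeks)
    taxa = sorted(set(cover["taxon"]))
    pnht = np.zeros((len(taxa), len(weeks)))
    active = []
    for i, t in enumerate(taxa):
        p = pnt.get(t)
        if p is None or np.isnan(p):
            continue
        active.append(t)
        cal = calendars[t]
        pnht[i] = [weekly_nectar_potential(p, cal, w) for w in weeks]
    t_index = {t: i for i, t in enumerate(taxa)}

    # base term per (luu, taxon): decay * S * Rt/100
    base = np.empty(len(cover))
    rowtax = np.empty(len(cover), dtype=int)
    lus_col = []
    for k, r in enumerate(cover.itertuples(index=False)):
        lus, s_ha, w = luu_info[r.luu_id]
        rt = float(r.rt_pct)
        if not 0.0 <= rt <= 100.0:
            raise ValueError(f"cover outside [0, 100] for {r.taxon!r}")
        base[k] = w * s_ha * rt / 100.0
        rowtax[k] = t_index[r.taxon]
        lus_col.append(lus)

    contrib = base[:, None] * pnht[rowtax]  # (rows, weeks)

    cdf = pd.DataFrame(contrib, columns=list(weeks))
    cdf.insert(0, "luu_id", cover["luu_id"].to_numpy())
    cdf.insert(1, "lus", lus_col)
    cdf.insert(2, "taxon", cover["taxon"].to_numpy())

    # per (luu, week)
    luu_week = (
        cdf.drop(columns=["taxon"])
        .groupby(["luu_id", "lus"], sort=True, as_index=False)
        .sum()
        .melt(id_vars=["luu_id", "lus"], var_name="week", value_name="hpp_kg")
    )
    luu_week["week"] = luu_week["week"].astype(int)
    # make the frame total over LUUs: zero rows for patches with no flora
    scored = set(luu_week["luu_id"])
    zrows = [
        (u.luu_id, u.lus, w, 0.0)
        for u in landscape.luus
        if u.luu_id not in scored
        for w in weeks
    ]
    if zrows:
        luu_week = pd.concat(
            [luu_week, pd.DataFrame(zrows, columns=luu_week.columns)],
            ignore_index=True,
        )
    luu_week = luu_week.sort_values(["luu_id", "week"], ignore_index=True)

    # per (lus, week), with per-area normalisation by total station area
    lus_area_ha = {
        lus: sum(u.area_ha for u in landscape.by_lus(lus))
        for lus in landscape.lus_present()
    }
    per_lus = (
        luu_week.groupby(["lus", "week"], sort=True, as_index=False)["hpp_kg"].sum()
    )
    per_lus["hpp_kg_per_ha"] = per_lus.apply(
        lambda r: r["hpp_kg"] / lus_area_ha[r["lus"]], axis=1
    )

    per_taxon_lus = (
        cdf.assign(hpp_kg=contrib.sum(axis=1))
        .groupby(["taxon", "lus"], sort=True, as_index=False)["hpp_kg"]
        .sum()
    )
    per_taxon = (
        per_taxon_lus.groupby("taxon", sort=True, as_index=False)["hpp_kg"].sum()
    )

    return WeeklyHPPSurface(luu_week, per_lus, per_taxon, per_taxon_lus, weeks)


def rank_taxa(surface: WeeklyHPPSurface, k: int) -> pd.DataFrame:
    """Top-k taxa by cumulative HPP (ties broken alphabetically)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = surface.per_taxon.sort_values(
        ["hpp_kg", "taxon"], ascending=[False, True], ignore_index=True
    )
    return df.head(k)


def lus_share_of_taxon(surface: WeeklyHPPSurface, taxon: str) -> dict[str, float]:
    """Percent of a taxon's cumulative HPP attributed to each station."""
    sub = surface.per_taxon_lus[surface.per_taxon_lus["taxon"] == taxon]
    total = float(sub["hpp_kg"].sum())
    if not len(sub) or total <= 0.0:
        raise ValueError(f"taxon {taxon!r} has no HPP contribution")
    return {
        str(r.lus): 100.0 * float(r.hpp_kg) / total
        for r in sub.itertuples(index=False)
    }


def rasterize(
    surface: WeeklyHPPSurface,
    landscape: Landscape,
    week: int,
    cell_size: float,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Grid the weekly HPP surface by cell-centre containment.

    Returns ``(grid, (xmin, ymin, cell_size))`` with row 0 at the top
    (north); cells whose centre falls outside every patch are NaN.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    import shapely

    minx, miny, maxx, maxy = shapely.unary_union(
        [u.polygon for u in landscape.luus]
    ).bounds
    ncol = int(np.ceil((maxx - minx) / cell_size))
    nrow = int(np.ceil((maxy - miny) / cell_size))
    xs = minx + (np.arange(ncol) + 0.5) * cell_size
    ys = miny + (np.arange(nrow) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))

    wk = surface.luu_week[surface.luu_week["week"] == week]
    hpp_by_luu = dict(zip(wk["luu_id"], wk["hpp_kg"]))

    tree = STRtree([u.polygon for u in landscape.luus])
    pidx, gidx = tree.query(pts, predicate="intersects")
    flat = np.full(nrow * ncol, np.nan)
    seen: dict[int, int] = {}
    for p, g in zip(pidx.tolist(), gidx.tolist()):
        if p not in seen or g < seen[p]:
            seen[p] = g
    for p, g in seen.items():
        flat[p] = hpp_by_luu.get(landscape.luus[g].luu_id, 0.0)
    grid = flat.reshape(nrow, ncol)[::-1]  # row 0 = top
    return grid, (float(minx), float(miny), float(cell_size))


def write_ascii_grid(
    path, grid: np.ndarray, origin: tuple[float, float, float], nodata: float = -9999.0
) -> None:
    """Write a grid as an ESRI ASCII raster (plain-text georeferenced)."""
    xmin, ymin, cell = origin
    nrow, ncol = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncol}\nnrows {nrow}\nxllcorner {xmin}\nyllcorner {ymin}\n"
            f"cellsize {cell}\nNODATA_value {nodata}\n"
        )
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
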