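"""Seeded synthetic foraging-area generator.

Emulates the data a field campaign around one apiary would produce: a
~707 ha circular foraging area (radius 1.5 km) tiled by land-use patches
(LUUs) with prescribed per-class patch counts and area shares, a
systematic grid of botanical survey plots with Braun-Blanquet cover
records, per-taxon nectariferous potentials, and weekly flowering
calendars over weeks 10-34.

Construction: the disc is cut into vertical bands whose areas equal the
requested per-class shares exactly (band edges found by bisection on the
clipped area), each class's share being split over several interleaved
bands so its patches are scattered across the area; each band is then
tessellated into the requested number of patches by a Voronoi diagram of
uniformly seeded points. Riparian forest receives many very narrow bands,
giving the stream-corridor geometry typical of that class. The result has
*exact* patch counts and area shares, irregular convex patches, and is a
deterministic function of (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq
from shapely import STRtree, affinity
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .landscape import LUS_LABELS, LUU, Landscape, M2_PER_HA, UNSURVEYED_LUS
from .flora import (
    ObservationPlot,
    PhenologyCalendar,
    WEEKS,
    BRAUN_BLANQUET_COVER,
)

_WEEK_MIN, _WEEK_MAX = WEEKS[0], WEEKS[-1]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic foraging area.

    Defaults reproduce the study conditions of a heterogeneous
    peripannonian mosaic: 707 ha (a 1.5 km-radius foraging disc), eight
    land-use stations with the patch counts and area shares of the mapped
    area, a ~160-species melliferous pool with strong richness contrasts
    between land uses, and staggered flowering windows that concentrate
    orchard bloom early, forest bloom in late spring, and grassland bloom
    through summer.
    """

    total_area_ha: float = 707.0
    lus_shares: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 0.363,
            "grassland": 0.261,
            "habitation": 0.1251,  # remainder so shares sum to 1
            "wasteland": 0.0906,
            "orchard": 0.0611,
            "cropfield": 0.0417,
            "maize": 0.0404,
            "riparian": 0.0171,
        }
    )
    lus_patch_counts: dict[str, int] = field(
        default_factory=lambda: {
            "forest": 40,
            "grassland": 114,
            "habitation": 55,
            "wasteland": 38,
            "orchard": 132,
            "cropfield": 43,
            "maize": 49,
            "riparian": 13,
        }
    )
    species_pool_size: int = 162
    richness_by_lus: dict[str, float] = field(
        default_factory=lambda: {
            "forest": 5.39,
            "wasteland": 5.78,
            "grassland": 14.4,
            "riparian": 16.7,
            "orchard": 6.0,
            "maize": 3.0,
        }
    )
    community_size_by_lus: dict[str, int] = field(
        default_factory=lambda: {
            "forest": 66,
            "wasteland": 50,
            "grassland": 84,
            "riparian": 69,
            "orchard": 45,
            "maize": 25,
        }
    )
    pnt_range: tuple[float, float] = (0.5, 800.0)  # kg/ha, log-uniform
    flowering_onset_range: tuple[int, int] = (10, 30)
    flowering_duration_range: tuple[int, int] = (2, 8)
    #: Onset windows per primary land use; stagger bloom into the
    #: orchard -> forest -> mixed -> grassland seasonal succession.
    onset_window_by_lus: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "orchard": (11, 15),
            "forest": (12, 24),
            "riparian": (14, 26),
            "wasteland": (18, 28),
            "grassland": (16, 30),
            "maize": (20, 26),
        }
    )
    plot_spacing: float = 150.0  # m, systematic survey grid
    #: Probability that a candidate grid point on a surveyable LUU could
    #: actually be reached and determined in the field.
    accessibility: float = 0.55
    excluded_frac: float = 0.08  # taxa with no published potential
    genus_fallback_frac: float = 0.05  # potentials borrowed from the genus
    bb_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "r": 0.10, "+": 0.20, "1": 0.30, "2": 0.20,
            "3": 0.10, "4": 0.06, "5": 0.04,
        }
    )
    stratum_by_lus: dict[str, str] = field(
        default_factory=lambda: {
            "forest": "tree",
            "riparian": "tree",
            "orchard": "tree",
            "wasteland": "shrub",
            "grassland": "herb",
            "maize": "herb",
        }
    )
    min_patch_area_m2: float = 100.0
    rng_seed: int = 0

    def validate(self) -> None:
        s = sum(self.lus_shares.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"lus_shares sum to {s!r}, expected 1")
        for lus, share in self.lus_shares.items():
            if lus not in LUS_LABELS:
                raise ValueError(f"unknown LUS {lus!r} in lus_shares")
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"share for {lus!r} outside [0, 1]")
            n = self.lus_patch_counts.get(lus, 0)
            if share > 0 and n < 1:
                raise ValueError(f"LUS {lus!r} has nonzero share but no patches")
            if share == 0 and n > 0:
                raise ValueError(f"LUS {lus!r} has patches but zero share")
        lo, hi = self.flowering_onset_range
        if not (_WEEK_MIN <= lo <= hi <= _WEEK_MAX):
            raise ValueError("flowering onset range outside weeks 10-34")
        dlo, dhi = self.flowering_duration_range
        if not (1 <= dlo <= dhi <= len(WEEKS)):
            raise ValueError("flowering duration range infeasible")
        for lus, (a, b) in self.onset_window_by_lus.items():
            if not (_WEEK_MIN <= a <= b <= _WEEK_MAX):
                raise ValueError(f"onset window for {lus!r} outside weeks 10-34")
        p = sum(self.bb_class_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError("bb_class_probs must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pnt_range"] = list(self.pnt_range)
        d["flowering_onset_range"] = list(self.flowering_onset_range)
        d["flowering_duration_range"] = list(self.flowering_duration_range)
        d["onset_window_by_lus"] = {
            k: list(v) for k, v in self.onset_window_by_lus.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kw = dict(d)
        for key in ("pnt_range", "flowering_onset_range", "flowering_duration_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "onset_window_by_lus" in kw:
            kw["onset_window_by_lus"] = {
                k: tuple(v) for k, v in kw["onset_window_by_lus"].items()
            }
        cfg = cls(**kw)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Landscape construction
# ---------------------------------------------------------------------------


def disc_polygon(area_ha: float) -> Polygon:
    """A polygonal disc centred on the origin with exactly this area."""
    target = area_ha * M2_PER_HA
    r = math.sqrt(target / math.pi)
    disc = Point(0.0, 0.0).buffer(r, quad_segs=128)
    k = math.sqrt(target / disc.area)  # correct polygonal approximation
    return affinity.scale(disc, xfact=k, yfact=k, origin=(0.0, 0.0))


def _left_area(region: Polygon, x: float, pad: float) -> float:
    minx, miny, maxx, maxy = region.bounds
    if x <= minx:
        return 0.0
    return region.intersection(box(minx - pad, miny - pad, x, maxy + pad)).area


def _band_edges(region: Polygon, shares: Sequence[float]) -> list[float]:
    """x-coordinates cutting ``region`` into bands of the given area shares."""
    minx, _, maxx, _ = region.bounds
    pad = 1.0
    total = region.area
    edges = [minx]
    cum = 0.0
    for s in shares[:-1]:
        cum += s
        target = cum * total
        lo = edges[-1]
        edges.append(
            brentq(lambda x: _left_area(region, x, pad) - target, lo, maxx, xtol=1e-9)
        )
    edges.append(maxx)
    return edges


def _n_chunks(lus: str, n: int) -> int:
    # riparian forest: many narrow bands -> stream-corridor geometry
    if lus == "riparian":
        return max(2, n // 3) if n > 1 else 1
    return max(1, n // 12)


def _sample_in(region: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = region.bounds
    pts: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(region, xs, ys)
        cand = np.column_stack([xs[keep], ys[keep]])
        for row in cand:
            if got >= n:
                break
            if all(np.hypot(*(row - p)) > 1e-3 for p in pts):
                pts.append(row)
                got += 1
    return np.asarray(pts)


def _voronoi_cells(region: Polygon, seeds: np.ndarray) -> list[Polygon]:
    """Voronoi cells of ``seeds`` clipped to a convex ``region``, seed order."""
    if len(seeds) == 1:
        return [region]
    vd = voronoi_diagram(MultiPoint([tuple(p) for p in seeds]), envelope=region)
    cells: list[Polygon | None] = [None] * len(seeds)
    raw = list(vd.geoms)
    for cell in raw:
        for i, p in enumerate(seeds):
            if cells[i] is None and cell.intersects(Point(p)):
                cells[i] = cell
                break
    out: list[Polygon] = []
    for i, cell in enumerate(cells):
        if cell is None:  # pragma: no cover - degenerate seed geometry
            raise RuntimeError("Voronoi cell/seed matching failed")
        clipped = cell.intersection(region)
        if clipped.geom_type == "MultiPolygon":  # numerical slivers
            clipped = max(clipped.geoms, key=lambda g: g.area)
        out.append(Polygon(clipped))
    return out


def generate_landscape(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> Landscape:
    """Generate the polygonal land-use mosaic of the foraging area.

    Returns a :class:`~melliflow.landscape.Landscape` whose per-LUS patch
    counts equal ``config.lus_patch_counts`` exactly and whose per-LUS
    areas equal ``config.lus_shares`` x ``config.total_area_ha`` to
    numerical precision. The apiary sits at the region centroid.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng((config.rng_seed, 0))

    total_m2 = config.total_area_ha * M2_PER_HA
    for lus, share in config.lus_shares.items():
        n = config.lus_patch_counts.get(lus, 0)
        if n and share * total_m2 < n * config.min_patch_area_m2:
            raise ValueError(
                f"infeasible tessellation for LUS {lus!r}: {n} patches need at "
                f"least {n * config.min_patch_area_m2:.0f} m^2 but the share "
                f"provides {share * total_m2:.0f} m^2"
            )

    region = disc_polygon(config.total_area_ha)

    # split every LUS into interleaved band chunks
    chunks: list[tuple[str, int, float]] = []  # (lus, n_patches, share)
    for lus in LUS_LABELS:
        share = config.lus_shares.get(lus, 0.0)
        n = config.lus_patch_counts.get(lus, 0)
        if n == 0 or share == 0.0:
            continue
        k = _n_chunks(lus, n)
        base, rem = divmod(n, k)
        counts = [base + (1 if i < rem else 0) for i in range(k)]
        for c in counts:
            chunks.append((lus, c, share * c / n))
    order = rng.permutation(len(chunks))
    chunks = [chunks[i] for i in order]

    edges = _band_edges(region, [c[2] for c in chunks])
    minx, miny, maxx, maxy = region.bounds
    pad = 1.0

    luus: list[LUU] = []
    counter = 0
    for (lus, n_patches, _), x0, x1 in zip(chunks, edges[:-1], edges[1:]):
        band = region.intersection(box(x0, miny - pad, x1, maxy + pad))
        seeds = _sample_in(band, n_patches, rng)
        for cell in _voronoi_cells(band, seeds):
            counter += 1
            luus.append(LUU(f"L{counter:04d}", lus, cell))

    return Landscape(luus, apiary=Point(0.0, 0.0))


# ---------------------------------------------------------------------------
# Survey, traits and phenology
# ---------------------------------------------------------------------------


def _make_calendar(
    taxon: str, onset: int, duration: int
) -> PhenologyCalendar:
    """One contiguous flowering window; edge weeks early/late, interior full.

    A 1-week window is a single full week; a 2-week window is early+late.
    """
    end = min(_WEEK_MAX, onset + duration - 1)
    weeks = list(range(onset, end + 1))
    phases: dict[int, str] = {}
    if len(weeks) == 1:
        phases[weeks[0]] = "full"
    else:
        phases[weeks[0]] = "early"
        phases[weeks[-1]] = "late"
        for w in weeks[1:-1]:
            phases[w] = "full"
    return PhenologyCalendar(taxon, phases)


def generate_survey(
    landscape: Landscape,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ObservationPlot], pd.DataFrame, dict[str, PhenologyCalendar]]:
    """Generate survey plots, taxon traits, and flowering calendars.

    Plots sit on a regular grid of ``config.plot_spacing`` metres anchored
    at the apiary; grid points on habitation or grass-cropfield patches
    are never surveyed, and the rest are retained with probability
    ``config.accessibility`` (field accessibility). Each plot draws taxa
    from its land-use community so that expected per-plot richness matches
    ``config.richness_by_lus``. Grasses are not part of the species pool,
    mirroring their exclusion from the botanical records.

    Returns ``(plots, traits, calendars)`` where ``traits`` has columns
    ``taxon, pnt_kg_ha, provenance`` (provenance in {species-level,
    genus-fallback, excluded}; excluded taxa carry NaN potential) and
    ``calendars`` maps taxon name to its :class:`PhenologyCalendar`.
    """
    config.validate()
    if not landscape.luus:
        raise ValueError("landscape is empty")
    if rng is None:
        rng = np.random.default_rng((config.rng_seed, 1))

    # --- candidate grid -------------------------------------------------
    s = config.plot_spacing
    cx, cy = landscape.apiary.x, landscape.apiary.y
    minx, miny, maxx, maxy = shapely.unary_union(
        [u.polygon for u in landscape.luus]
    ).bounds
    kx0 = math.floor((minx - cx) / s)
    kx1 = math.ceil((maxx - cx) / s)
    ky0 = math.floor((miny - cy) / s)
    ky1 = math.ceil((maxy - cy) / s)
    grid = [
        (cx + (i + 0.5) * s, cy + (j + 0.5) * s)
        for j in range(ky0, ky1 + 1)
        for i in range(kx0, kx1 + 1)
    ]
    pts = shapely.points(np.asarray(grid)) if grid else np.array([])
    tree = STRtree([u.polygon for u in landscape.luus])
    luu_of: dict[int, int] = {}
    if len(grid):
        pidx, gidx = tree.query(pts, predicate="intersects")
        for p, g in zip(pidx.tolist(), gidx.tolist()):
            if p not in luu_of or g < luu_of[p]:
                luu_of[p] = g

    # --- species pool, communities, traits, calendars -------------------
    width = max(3, len(str(config.species_pool_size)))
    pool = [f"taxon_{i:0{width}d}" for i in range(1, config.species_pool_size + 1)]
    communities: dict[str, list[str]] = {}
    primary: dict[str, str] = {}
    for lus in LUS_LABELS:
        if lus in UNSURVEYED_LUS:
            continue
        size = min(config.community_size_by_lus.get(lus, 30), len(pool))
        comm = sorted(rng.choice(pool, size=size, replace=False).tolist())
        communities[lus] = comm
        for t in comm:
            primary.setdefault(t, lus)

    log_lo, log_hi = (math.log(v) for v in config.pnt_range)
    trows = []
    calendars: dict[str, PhenologyCalendar] = {}
    dlo, dhi = config.flowering_duration_range
    for taxon in pool:
        pnt = math.exp(rng.uniform(log_lo, log_hi))
        u = rng.random()
        if u < config.excluded_frac:
            provenance, pnt_out = "excluded", float("nan")
        elif u < config.excluded_frac + config.genus_fallback_frac:
            provenance, pnt_out = "genus-fallback", pnt
        else:
            provenance, pnt_out = "species-level", pnt
        trows.append((taxon, pnt_out, provenance))
        lo, hi = config.onset_window_by_lus.get(
            primary.get(taxon, ""), config.flowering_onset_range
        )
        onset = int(rng.integers(lo, hi + 1))
        duration = int(rng.integers(dlo, dhi + 1))
        calendars[taxon] = _make_calendar(taxon, onset, duration)
    traits = pd.DataFrame(trows, columns=["taxon", "pnt_kg_ha", "provenance"])

    # --- plots -----------------------------------------------------------
    bb_classes = list(config.bb_class_probs)
    bb_probs = np.asarray([config.bb_class_probs[c] for c in bb_classes])
    plots: list[ObservationPlot] = []
    for p_idx in range(len(grid)):
        g = luu_of.get(p_idx)
        if g is None:
            continue
        luu = landscape.luus[g]
        if luu.lus in UNSURVEYED_LUS:
            continue
        if rng.random() >= config.accessibility:
            continue
        comm = communities.get(luu.lus)
        if not comm:
            continue
        mean_rich = config.richness_by_lus.get(luu.lus, 5.0)
        k = int(np.clip(rng.poisson(mean_rich), 1, len(comm)))
        taxa = sorted(rng.choice(comm, size=k, replace=False).tolist())
        recs = tuple(
            (t, str(rng.choice(bb_classes, p=bb_probs))) for t in taxa
        )
        x, y = grid[p_idx]
        plots.append(
            ObservationPlot(
                plot_id=f"P{len(plots) + 1:03d}",
                x=x,
                y=y,
                stratum=config.stratum_by_lus.get(luu.lus, "herb"),
                luu_id=luu.luu_id,
                records=recs,
            )
        )
    if not plots:
        warnings.warn(
            "plot spacing exceeds the landscape extent: zero plots generated",
            stacklevel=2,
        )
    return plots, traits, calendars
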