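"""Landscape composition and fragmentation indices.

Per land-use station i the module reports the Fragstats-style indices:
mean patch area Si = sum_j a_ij / n_i (ha), patch density
Dti = n_i / A * 10,000 * 100 (patches per 100 ha, A in m^2), and mean
Euclidean nearest-neighbour distance ENNi = mean_j d_ij (m), where d_ij
is the minimum edge-to-edge distance from patch j to the closest other
patch of the same station. Same-station patches that touch are kept
distinct (no dissolve) and contribute d_ij = 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely import STRtree

from .landscape import LUS_LABELS, Landscape, M2_PER_HA


def composition(landscape: Landscape) -> dict[str, float]:
    """Percent of total landscape area per land-use station."""
    if not landscape.luus:
        raise ValueError("empty landscape")
    total = landscape.total_area_m2
    out: dict[str, float] = {}
    for lus in landscape.lus_present():
        out[lus] = 100.0 * sum(u.area_m2 for u in landscape.by_lus(lus)) / total
    return out


def mean_patch_area(landscape: Landscape, lus: str) -> tuple[float, float]:
    """Mean patch area Si (ha) and sample SD for one station.

    SD uses n-1 degrees of freedom; a single-patch station reports SD 0.
    """
    patches = landscape.by_lus(lus)
    if not patches:
        raise ValueError(f"LUS {lus!r} has no patches in this landscape")
    areas = np.asarray([u.area_ha for u in patches])
    sd = float(areas.std(ddof=1)) if len(areas) > 1 else 0.0
    return float(areas.mean()), sd


def patch_density(landscape: Landscape, lus: str) -> float:
    """Patch density Dti (patches per 100 ha of total landscape)."""
    a_m2 = landscape.total_area_m2
    if a_m2 <= 0:
        raise ValueError("landscape has zero total area")
    n = len(landscape.by_lus(lus))
    return n / a_m2 * M2_PER_HA * 100.0


def nearest_neighbor_distances(landscape: Landscape, lus: str) -> np.ndarray:
    """Per-patch distance d_ij to the nearest same-station patch (m).

    Edge-to-edge (minimum boundary) distances; adjacent patches give 0.
    Empty array when the station has fewer than two patches.
    """
    patches = landscape.by_lus(lus)
    if len(patches) < 2:
        return np.empty(0)
    geoms = [u.polygon for u in patches]
    tree = STRtree(geoms)
    dists = np.empty(len(geoms))
    for i, g in enumerate(geoms):
        _, d = tree.query_nearest(
            g, exclusive=True, all_matches=False, return_distance=True
        )
        dists[i] = float(d[0])
    return dists


def mean_nearest_neighbor(landscape: Landscape, lus: str) -> tuple[float, float]:
    """Mean ENNi and sample SD (m); NaN with a warning when n_i < 2."""
    d = nearest_neighbor_distances(landscape, lus)
    if d.size == 0:
        warnings.warn(
            f"ENN undefined for LUS {lus!r} with fewer than 2 patches",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def metrics_table(landscape: Landscape) -> pd.DataFrame:
    """Full landscape-characterisation table, one row per station.

    Columns: ``lus, n_luu, si_ha, si_sd_ha, dti_per_100ha, enn_m,
    enn_sd_m, share_pct``.
    """
    comp = composition(landscape)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lus in landscape.lus_present():
            si, si_sd = mean_patch_area(landscape, lus)
            enn, enn_sd = mean_nearest_neighbor(landscape, lus)
            rows.append(
                (
                    lus,
                    len(landscape.by_lus(lus)),
                    si,
                    si_sd,
                    patch_density(landscape, lus),
                    enn,
                    enn_sd,
                    comp[lus],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lus",
            "n_luu",
            "si_ha",
            "si_sd_ha",
            "dti_per_100ha",
            "enn_m",
            "enn_sd_m",
            "share_pct",
        ],
    )
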