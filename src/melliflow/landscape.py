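"""Landscape domain model: Land Use Units, Land Use Stations, GeoJSON I/O.

A foraging area is modelled as a mosaic of contiguous land-use patches.
Each patch is a *Land Use Unit* (LUU); the (possibly discontinuous) union
of all patches sharing one land-use class is a *Land Use Station* (LUS).
Eight LUS classes are recognised: forest, grassland, wasteland, riparian
forest, arable cropfields excluding maize, maize, orchard, and
habitation/other. All coordinates are planar metric (metres); inputs in
geographic coordinates must be re-projected before entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from shapely import STRtree
from shapely.geometry import Point, Polygon, mapping, shape

#: The closed set of land-use station labels.
LUS_LABELS: tuple[str, ...] = (
    "forest",
    "grassland",
    "wasteland",
    "riparian",
    "cropfield",  # arable crops excluding maize
    "maize",
    "orchard",
    "habitation",  # habitations and other non-vegetated use
)

#: LUS classes never surveyed botanically (inaccessible or non-melliferous).
UNSURVEYED_LUS: frozenset[str] = frozenset({"habitation", "cropfield"})

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class LUU:
    """One contiguous land-use patch.

    Parameters
    ----------
    luu_id:
        Unique identifier within the landscape.
    lus:
        Land-use station label, one of :data:`LUS_LABELS`.
    polygon:
        Patch geometry in planar metric coordinates (m).
    """

    luu_id: str
    lus: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.lus not in LUS_LABELS:
            raise ValueError(f"unknown LUS label {self.lus!r}")
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError(f"LUU {self.luu_id!r} has non-positive area")
        if not self.polygon.is_valid:
            raise ValueError(f"LUU {self.luu_id!r} polygon is invalid")

    @property
    def area_m2(self) -> float:
        """Patch surface area (m^2)."""
        return self.polygon.area

    @property
    def area_ha(self) -> float:
        """Patch surface area (ha)."""
        return self.polygon.area / M2_PER_HA

    @property
    def centroid(self) -> Point:
        """Area centroid ("centre of gravity") of the patch."""
        return self.polygon.centroid


@dataclass
class Landscape:
    """A foraging-area mosaic: a set of LUUs plus the apiary location.

    The apiary is the point around which honey production potential is
    scored; distances to it enter the HPP distance-decay factor.
    """

    luus: list[LUU]
    apiary: Point
    crs_note: str = "planar metric coordinates (m)"

    def __iter__(self) -> Iterator[LUU]:
        return iter(self.luus)

    def __len__(self) -> int:
        return len(self.luus)

    @property
    def total_area_m2(self) -> float:
        return sum(u.area_m2 for u in self.luus)

    @property
    def total_area_ha(self) -> float:
        return self.total_area_m2 / M2_PER_HA

    def by_lus(self, lus: str) -> list[LUU]:
        """All patches of one land-use station, in insertion order."""
        return [u for u in self.luus if u.lus == lus]

    def lus_present(self) -> list[str]:
        """LUS labels present, in the canonical order of :data:`LUS_LABELS`."""
        present = {u.lus for u in self.luus}
        return [l for l in LUS_LABELS if l in present]

    def get(self, luu_id: str) -> LUU:
        for u in self.luus:
            if u.luu_id == luu_id:
                return u
        raise KeyError(luu_id)

    def validate(self, overlap_tol_m2: float = 1e-6) -> None:
        """Check structural invariants.

        Raises ``ValueError`` on duplicate ids or on any pair of patches
        overlapping by more than ``overlap_tol_m2`` square metres.
        """
        ids = [u.luu_id for u in self.luus]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate luu_id values")
        geoms = [u.polygon for u in self.luus]
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g, predicate="intersects"):
                if j <= i:
                    continue
                inter = g.intersection(geoms[j])
                if inter.area > overlap_tol_m2:
                    raise ValueError(
                        f"LUUs {ids[i]!r} and {ids[int(j)]!r} overlap by "
                        f"{inter.area:.3g} m^2"
                    )


def to_geojson(landscape: Landscape) -> dict:
    """Serialise a landscape to a GeoJSON FeatureCollection mapping.

    LUU polygons carry ``luu_id`` and ``lus`` properties; the apiary is a
    Point feature with ``kind: "apiary"``.
    """
    features = [
        {
            "type": "Feature",
            "geometry": mapping(u.polygon),
            "properties": {"luu_id": u.luu_id, "lus": u.lus},
        }
        for u in landscape.luus
    ]
    features.append(
        {
            "type": "Feature",
            "geometry": mapping(landscape.apiary),
            "properties": {"kind": "apiary"},
        }
    )
    return {
        "type": "FeatureCollection",
        "crs_note": landscape.crs_note,
        "features": features,
    }


def from_geojson(obj: dict) -> Landscape:
    """Rebuild a :class:`Landscape` from :func:`to_geojson` output."""
    luus: list[LUU] = []
    apiary: Point | None = None
    for feat in obj["features"]:
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("kind") == "apiary":
            apiary = Point(geom)
        else:
            luus.append(LUU(str(props["luu_id"]), props["lus"], Polygon(geom)))
    if apiary is None:
        raise ValueError("GeoJSON landscape has no apiary point feature")
    return Landscape(luus, apiary, obj.get("crs_note", "planar metric coordinates (m)"))


def write_geojson(landscape: Landscape, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_geojson(landscape), fh)
        fh.write("\n")


def read_geojson(path) -> Landscape:
    with open(path) as fh:
        return from_geojson(json.load(fh))
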