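"""Georeferenced tree placement: canopy-buffer conflicts and Autogrid fill.

All coordinates are WGS84 decimal degrees; distances are great-circle
(haversine) on a sphere of radius 6,371,000 m. A planted tree carries a
canopy *buffer*: the circle of radius diameter/2 around its location, where
diameter equals the species' maximum canopy width. Two placement conflict
rules exist:

* ``point_in_buffer`` — a candidate point falls strictly inside an existing
  tree's buffer (the click-inside-a-circle warning);
* ``canopy_overlap`` — two canopies intersect, i.e. center distance is
  strictly less than the sum of the two radii.

Autogrid fills a user polygon deterministically: a grid spaced by the
largest requested canopy width is laid over the polygon's bounding box,
grid nodes inside the polygon are traversed row-major from the north-west
corner, and species requests are served round-robin (largest canopy first),
each tree taking the first candidate that passes the overlap audit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon as ShapelyPolygon, shape
from shapely.validation import explain_validity

from .errors import LookupError_, PlacementConflictError, ValidationError
from .traits import TraitDatabase, cooling_index

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range [-90, 90]: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude out of range [-180, 180]: {self.longitude}")


@dataclass(frozen=True)
class PlantedTree:
    species: str
    location: GeoPoint
    diameter: float  # canopy size in meters (= species CW)
    cooling_index: float  # °C

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValidationError(f"{self.species}: diameter must be > 0")
        if not 2.0 <= self.cooling_index <= 8.0:
            raise ValidationError(
                f"{self.species}: cooling_index {self.cooling_index} outside [2, 8]"
            )


@dataclass
class PlantingLayout:
    trees: list[PlantedTree] = field(default_factory=list)

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trees:
            counts[t.species] = counts.get(t.species, 0) + 1
        return counts


@dataclass
class Polygon2D:
    """Simple ring polygon in lon/lat, implicitly closed, validated non-self-intersecting."""

    vertices: list[GeoPoint]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValidationError("polygon needs >= 3 vertices")
        poly = self._shapely()
        if not poly.is_valid:
            raise ValidationError(f"invalid polygon: {explain_validity(poly)}")
        if poly.area == 0:
            raise ValidationError("degenerate polygon with zero area")

    def _shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon([(v.longitude, v.latitude) for v in self.vertices])

    @classmethod
    def from_geojson(cls, path: str | Path) -> "Polygon2D":
        """Read the first Polygon from a GeoJSON file (WGS84 lon/lat order)."""
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            gj = gj["features"][0]
        if gj.get("type") == "Feature":
            gj = gj["geometry"]
        geom = shape(gj)
        if geom.geom_type != "Polygon":
            raise ValidationError(f"expected a GeoJSON Polygon, got {geom.geom_type}")
        ring = list(geom.exterior.coords)
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        return cls([GeoPoint(latitude=lat, longitude=lon) for lon, lat in ring])

    def to_geojson(self, path: str | Path) -> None:
        ring = [[v.longitude, v.latitude] for v in self.vertices]
        ring.append(ring[0])
        with open(path, "w") as fh:
            json.dump({"type": "Polygon", "coordinates": [ring]}, fh)


@dataclass(frozen=True)
class ConflictResult:
    kind: str  # none | point_in_buffer | canopy_overlap
    offending_tree: int | None  # index into the layout, nearest offender
    distance: float  # meters to the nearest tree (inf for an empty layout)


def haversine(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371,000 m."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def conflict_check(
    candidate: GeoPoint,
    candidate_diameter: float,
    layout: PlantingLayout,
    mode: str = "canopy_overlap",
) -> ConflictResult:
    """Check a candidate location against every tree in the layout.

    ``point_in_buffer`` flags trees whose buffer strictly contains the
    candidate point; ``canopy_overlap`` flags trees whose canopy circle
    would strictly intersect the candidate's. The nearest offender (or,
    when clear, the nearest tree) is reported with its distance.
    """
    if mode not in ("point_in_buffer", "canopy_overlap"):
        raise ValidationError(f"unknown conflict mode: {mode!r}")
    best_idx, best_dist = None, math.inf
    off_idx, off_dist = None, math.inf
    for i, tree in enumerate(layout):
        d = haversine(candidate, tree.location)
        if d < best_dist:
            best_idx, best_dist = i, d
        threshold = (
            tree.diameter / 2.0
            if mode == "point_in_buffer"
            else (tree.diameter + candidate_diameter) / 2.0
        )
        if d < threshold and d < off_dist:
            off_idx, off_dist = i, d
    if off_idx is not None:
        return ConflictResult(kind=mode, offending_tree=off_idx, distance=off_dist)
    return ConflictResult(kind="none", offending_tree=None, distance=best_dist)


def place_tree(
    layout: PlantingLayout,
    species: str,
    location: GeoPoint,
    db: TraitDatabase,
    strict: bool = False,
) -> PlantingLayout:
    """Append one tree of ``species`` at ``location``.

    Diameter is the species' canopy width and the cooling index comes from
    the trait database. A canopy overlap raises
    :class:`PlacementConflictError` when ``strict``; otherwise it is only
    logged as a warning, mirroring a non-blocking GUI warning.
    """
    sp = db.get(species)
    conflict = conflict_check(location, sp.canopy_width, layout, mode="canopy_overlap")
    if conflict.kind != "none":
        if strict:
            raise PlacementConflictError(
                f"canopy overlap with tree #{conflict.offending_tree} "
                f"at {conflict.distance:.2f} m",
                conflict,
            )
        logger.warning(
            "conflict detected: %s overlaps tree #%s (%.2f m apart); placed anyway",
            species,
            conflict.offending_tree,
            conflict.distance,
        )
    ci = cooling_index(sp.tree_height, sp.canopy_width, sp.leaf_area_index, db)
    layout.trees.append(
        PlantedTree(species=species, location=location, diameter=sp.canopy_width, cooling_index=ci)
    )
    return layout


def point_in_polygon(p: GeoPoint, poly: Polygon2D) -> bool:
    """Even–odd containment in the lon/lat plane; boundary points count inside."""
    return poly._shapely().covers(Point(p.longitude, p.latitude))


@dataclass
class FillReport:
    """Per-species placed vs requested counts from an Autogrid run."""

    placed: dict[str, int]
    requested: dict[str, int]

    @property
    def complete(self) -> bool:
        return all(self.placed.get(s, 0) == n for s, n in self.requested.items())

    @property
    def shortfall(self) -> dict[str, int]:
        return {
            s: n - self.placed.get(s, 0)
            for s, n in self.requested.items()
            if self.placed.get(s, 0) < n
        }


def _grid_candidates(poly: Polygon2D, spacing_m: float) -> list[GeoPoint]:
    """Grid nodes over the bounding box whose centers fall inside the polygon,
    row-major from the north-west corner."""
    shp = poly._shapely()
    lon_min, lat_min, lon_max, lat_max = shp.bounds
    lat_mid = (lat_min + lat_max) / 2.0
    dlat = math.degrees(spacing_m / EARTH_RADIUS_M)
    dlon = math.degrees(spacing_m / (EARTH_RADIUS_M * max(1e-9, math.cos(math.radians(lat_mid)))))
    lats = np.arange(lat_max, lat_min - dlat / 2.0, -dlat)
    lons = np.arange(lon_min, lon_max + dlon / 2.0, dlon)
    out = []
    for lat in lats:
        for lon in lons:
            if shp.covers(Point(lon, lat)):
                out.append(GeoPoint(latitude=float(lat), longitude=float(lon)))
    return out


def autogrid(
    poly: Polygon2D,
    requests: list[tuple[str, int]],
    db: TraitDatabase,
) -> tuple[PlantingLayout, FillReport]:
    """Deterministically fill a polygon with the requested species mix.

    Grid spacing equals the largest requested canopy width, so same-species
    neighbors can never overlap. Species are served round-robin in order of
    descending canopy width, each cycle placing one tree of every
    still-pending species at the first free candidate that passes the
    canopy-overlap audit against every tree already placed. Stops when all
    requests are met or candidates are exhausted; the report records any
    shortfall.
    """
    requested: dict[str, int] = {}
    for name, count in requests:
        if count < 1:
            raise ValidationError(f"requested count for {name!r} must be >= 1")
        db.get(name)  # raises LookupError_ for unknown species
        requested[name] = requested.get(name, 0) + int(count)
    if not requested:
        return PlantingLayout(), FillReport(placed={}, requested={})

    spacing = max(db.get(name).canopy_width for name in requested)
    candidates = _grid_candidates(poly, spacing)
    used = [False] * len(candidates)
    order = sorted(requested, key=lambda s: (-db.get(s).canopy_width, s))
    pending = dict(requested)
    layout = PlantingLayout()
    placed = {s: 0 for s in requested}

    progress = True
    while pending and progress:
        progress = False
        for name in order:
            if pending.get(name, 0) == 0:
                continue
            sp = db.get(name)
            for k, cand in enumerate(candidates):
                if used[k]:
                    continue
                if conflict_check(cand, sp.canopy_width, layout, "canopy_overlap").kind == "none":
                    used[k] = True
                    place_tree(layout, name, cand, db, strict=True)
                    placed[name] += 1
                    pending[name] -= 1
                    if pending[name] == 0:
                        del pending[name]
                    progress = True
                    break
    if pending:
        logger.warning("autogrid shortfall: %s", pending)
    return layout, FillReport(placed=placed, requested=requested)


_LAYOUT_COLUMNS = ("species", "latitude", "longitude", "size_m", "cooling_index")


def write_layout(layout: PlantingLayout, path: str | Path) -> None:
    """Write a layout CSV (species, latitude, longitude, size_m, cooling_index)."""
    pd.DataFrame(
        {
            "species": [t.species for t in layout],
            "latitude": [t.location.latitude for t in layout],
            "longitude": [t.location.longitude for t in layout],
            "size_m": [t.diameter for t in layout],
            "cooling_index": [t.cooling_index for t in layout],
        },
        columns=list(_LAYOUT_COLUMNS),
    ).to_csv(path, index=False, float_format="%.17g")


def read_layout(path: str | Path) -> PlantingLayout:
    """Read a layout CSV; malformed rows raise with their line number."""
    from .errors import SchemaError

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"layout CSV missing column(s): {missing}")
    trees = []
    for idx, row in df.iterrows():
        try:
            trees.append(
                PlantedTree(
                    species=str(row["species"]),
                    location=GeoPoint(float(row["latitude"]), float(row["longitude"])),
                    diameter=float(row["size_m"]),
                    cooling_index=float(row["cooling_index"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            # +2: header line and 1-based numbering
            raise ValidationError(f"layout line {idx + 2}: {exc}") from None
    return PlantingLayout(trees)
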