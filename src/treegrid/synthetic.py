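"""Seeded synthetic inputs: trait databases, LST rasters and layouts.

The generators emulate the inputs the planning engine consumes so every
module is testable without external data:

* trait databases with TH ~ U(5, 35) m, CW ~ U(3, 25) m, LAI ~ U(1, 9) —
  ranges chosen so the attainable shade index spans up to 875 m² and the
  cooling index its full 2–8 °C scale; genera and families are assigned
  sparsely (about two species per genus, two genera per family) so
  10:20:30-compliant layouts are constructible;
* land-surface-temperature rasters with a radially peaked urban-heat-island
  surface (hot core, cool edges) plus Gaussian noise, clipped to a range;
* planting layouts by conflict-free rejection sampling inside a polygon.

Every generator is deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cooling import LSTGrid
from .placement import (
    GeoPoint,
    PlantingLayout,
    Polygon2D,
    conflict_check,
    place_tree,
    point_in_polygon,
)
from .traits import SERVICE_CATALOGUE, SpeciesTrait, TraitDatabase

logger = logging.getLogger(__name__)

#: trait ranges (low, high) reproducing the dashboard score spans
TH_RANGE = (5.0, 35.0)
CW_RANGE = (3.0, 25.0)
LAI_RANGE = (1.0, 9.0)

_NON_BIRD_GROUPS = ("pollinators", "insects", "lizards", "mammals")


@dataclass
class SynthConfig:
    seed: int = 0
    n_species: int = 30
    raster_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.00027  # degrees; ~30 m at the equator
    lst_range: tuple[float, float] = (28.0, 44.0)
    bird_prob: float = 0.5

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if min(self.raster_shape) < 1 or self.pixel_size <= 0:
            raise ValueError("raster shape and pixel size must be positive")
        if not self.lst_range[0] < self.lst_range[1]:
            raise ValueError("lst_range low must be below high")


def gen_species_db(cfg: SynthConfig) -> TraitDatabase:
    """Generate a synthetic species trait database (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    catalogue = sorted(SERVICE_CATALOGUE)
    entries = []
    for i in range(cfg.n_species):
        th = float(rng.uniform(*TH_RANGE))
        cw = float(rng.uniform(*CW_RANGE))
        lai = float(rng.uniform(*LAI_RANGE))
        groups = set()
        if rng.random() < cfg.bird_prob:
            groups.add("birds")
        for g in _NON_BIRD_GROUPS:
            if rng.random() < 0.5:
                groups.add(g)
        n_serv = int(rng.integers(1, len(catalogue) + 1))
        services = rng.choice(catalogue, size=n_serv, replace=False)
        entries.append(
            SpeciesTrait(
                name=f"Species_{i:03d}",
                genus=f"Genus_{i // 2:03d}",
                family=f"Family_{i // 4:03d}",
                tree_height=th,
                canopy_width=cw,
                leaf_area_index=lai,
                faunal_groups=frozenset(groups),
                services=frozenset(str(s) for s in services),
            )
        )
    return TraitDatabase(entries)


def gen_lst_raster(cfg: SynthConfig, lat_origin: float = 30.35, lon_origin: float = 78.0) -> LSTGrid:
    """Urban-heat-island LST raster: radial peak at the center plus noise."""
    rng = np.random.default_rng(cfg.seed + 1)
    nr, nc = cfg.raster_shape
    lo, hi = cfg.lst_range
    rows, cols = np.mgrid[0:nr, 0:nc]
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    dist = np.hypot(rows - cy, cols - cx)
    dist_max = max(1.0, float(dist.max()))
    surface = hi - (hi - lo) * (dist / dist_max)  # hot center, cool edges
    noisy = surface + rng.normal(0.0, 0.02 * (hi - lo), size=surface.shape)
    return LSTGrid(
        np.clip(noisy, lo, hi).astype(np.float32),
        lon_origin=lon_origin,
        lat_origin=lat_origin,
        pixel_size=cfg.pixel_size,
    )


def gen_layout(
    poly: Polygon2D,
    db: TraitDatabase,
    n: int,
    seed: int = 0,
    max_attempts_per_tree: int = 200,
) -> PlantingLayout:
    """Rejection-sample ``n`` conflict-free trees inside a polygon.

    Species are drawn uniformly from the database. If the polygon cannot
    host ``n`` trees within the attempt budget, a partial layout is
    returned with a warning.
    """
    rng = np.random.default_rng(seed)
    shp = poly._shapely()
    lon_min, lat_min, lon_max, lat_max = shp.bounds
    names = [s.name for s in db.entries]
    layout = PlantingLayout()
    for _ in range(n):
        name = names[int(rng.integers(0, len(names)))]
        sp = db.get(name)
        placed = False
        for _ in range(max_attempts_per_tree):
            p = GeoPoint(
                latitude=float(rng.uniform(lat_min, lat_max)),
                longitude=float(rng.uniform(lon_min, lon_max)),
            )
            if not point_in_polygon(p, poly):
                continue
            if conflict_check(p, sp.canopy_width, layout, "canopy_overlap").kind == "none":
                place_tree(layout, name, p, db, strict=True)
                placed = True
                break
        if not placed:
            logger.warning(
                "gen_layout: placed %d of %d trees before exhausting attempts", len(layout), n
            )
            break
    return layout


def square_polygon(center_lat: float, center_lon: float, side_m: float) -> Polygon2D:
    """Axis-aligned square of the given side length, handy for tests and demos."""
    from .placement import EARTH_RADIUS_M
    import math

    half_lat = math.degrees(side_m / 2.0 / EARTH_RADIUS_M)
    half_lon = math.degrees(
        side_m / 2.0 / (EARTH_RADIUS_M * max(1e-9, math.cos(math.radians(center_lat))))
    )
    return Polygon2D(
        [
            GeoPoint(center_lat + half_lat, center_lon - half_lon),
            GeoPoint(center_lat + half_lat, center_lon + half_lon),
            GeoPoint(center_lat - half_lat, center_lon + half_lon),
            GeoPoint(center_lat - half_lat, center_lon - half_lon),
        ]
    )
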