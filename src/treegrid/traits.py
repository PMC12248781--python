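"""Species trait database and per-species derived ecological scores.

Each species carries three morphological traits — maximum tree height TH (m),
maximum canopy width CW (m) and leaf area index LAI (dimensionless) — plus the
faunal groups it supports and the ecosystem services it provides. From these
the module derives:

* shade index  SI = CW × TH (m²), a proxy for lateral canopy shading;
* carbon value tier (Low/Medium/High) from height tertiles of the database;
* ecosystem-service category from the count of distinct services;
* faunal biodiversity score = number of supported faunal groups (0–5);
* cooling index CI (°C), a weighted sum of min–max-normalized traits scaled
  to the 2–8 °C range of realistic urban canopy cooling:

      CI = 2 + 6 · (0.4·TH_n + 0.2·CW_n + 0.4·LAI_n)

  where x_n is (x − min)/(max − min) over the loaded database, clamped to
  [0, 1]; a constant trait column normalizes to 0.5 so it contributes its
  mid-weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDistributionError,
    LookupError_,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

FAUNAL_GROUPS = frozenset({"pollinators", "birds", "insects", "lizards", "mammals"})

SERVICE_CATALOGUE = frozenset(
    {
        "air quality",
        "biodiversity support",
        "bird feeding",
        "carbon sequestration",
        "erosion control",
        "pollination",
        "pest suppression",
        "runoff reduction",
        "uhi mitigation",
    }
)

#: CI weights on (TH, CW, LAI); they sum to 1.
CI_WEIGHTS = (0.4, 0.2, 0.4)
CI_MIN, CI_MAX = 2.0, 8.0

_REQUIRED_COLUMNS = (
    "species",
    "genus",
    "family",
    "tree_height_m",
    "canopy_width_m",
    "lai",
    "faunal_groups",
    "services",
)


@dataclass(frozen=True)
class SpeciesTrait:
    """One species' morphological and ecological attributes."""

    name: str
    genus: str
    family: str
    tree_height: float  # TH, maximum, meters
    canopy_width: float  # CW, maximum, meters
    leaf_area_index: float  # LAI, dimensionless
    faunal_groups: frozenset[str] = frozenset()
    services: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.tree_height > 0:
            raise ValidationError(f"{self.name}: tree_height must be > 0, got {self.tree_height}")
        if not self.canopy_width > 0:
            raise ValidationError(f"{self.name}: canopy_width must be > 0, got {self.canopy_width}")
        if self.leaf_area_index < 0:
            raise ValidationError(f"{self.name}: leaf_area_index must be >= 0")
        unknown = set(self.faunal_groups) - FAUNAL_GROUPS
        if unknown:
            raise ValidationError(f"{self.name}: unknown faunal group(s) {sorted(unknown)}")


@dataclass
class TraitDatabase:
    """A loaded species trait table with cached bounds and height tertiles."""

    entries: list[SpeciesTrait]
    trait_bounds: dict[str, tuple[float, float]] = field(init=False)
    height_tertiles: tuple[float, float] = field(init=False)
    _by_name: dict[str, SpeciesTrait] = field(init=False, repr=False)

    def __post_init__(self):
        names = [s.name for s in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate species name(s): {sorted(dupes)}")
        self._by_name = {s.name: s for s in self.entries}
        if self.entries:
            th = np.array([s.tree_height for s in self.entries])
            cw = np.array([s.canopy_width for s in self.entries])
            lai = np.array([s.leaf_area_index for s in self.entries])
            self.trait_bounds = {
                "tree_height": (float(th.min()), float(th.max())),
                "canopy_width": (float(cw.min()), float(cw.max())),
                "leaf_area_index": (float(lai.min()), float(lai.max())),
            }
            # linear-interpolation percentiles; ties at a boundary go low
            self.height_tertiles = (
                float(np.percentile(th, 33)),
                float(np.percentile(th, 66)),
            )
        else:
            self.trait_bounds = {}
            self.height_tertiles = (float("nan"), float("nan"))

    def __len__(self):
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> SpeciesTrait:
        try:
            return self._by_name[name]
        except KeyError:
            raise LookupError_(f"species not in trait database: {name!r}") from None


@dataclass(frozen=True)
class DerivedScores:
    """Bundle of the five per-species derived scores."""

    shade_index: float  # m²
    carbon_value: str  # Low | Medium | High
    ecosystem_category: str  # Low | Moderate | High
    faunal_score: int  # 0..5
    cooling_index: float  # °C, in [2, 8]


def _split_field(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return frozenset()
    return frozenset(p.strip().lower() for p in str(raw).split(";") if p.strip())


def load_trait_db(path: str | Path) -> TraitDatabase:
    """Load a species trait CSV into a :class:`TraitDatabase`.

    Expected columns: species, genus, family, tree_height_m, canopy_width_m,
    lai, faunal_groups (semicolon-separated), services (semicolon-separated).

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (naming the row) for non-positive traits or
    duplicated species names.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait CSV missing required column(s): {missing}")
    entries = []
    for idx, row in df.iterrows():
        try:
            entries.append(
                SpeciesTrait(
                    name=str(row["species"]),
                    genus=str(row["genus"]),
                    family=str(row["family"]),
                    tree_height=float(row["tree_height_m"]),
                    canopy_width=float(row["canopy_width_m"]),
                    leaf_area_index=float(row["lai"]),
                    faunal_groups=_split_field(row["faunal_groups"]),
                    services=_split_field(row["services"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
    return TraitDatabase(entries)


def write_trait_db(db: TraitDatabase, path: str | Path) -> None:
    """Write a trait database back to the CSV schema accepted by load_trait_db."""
    pd.DataFrame(
        {
            "species": [s.name for s in db.entries],
            "genus": [s.genus for s in db.entries],
            "family": [s.family for s in db.entries],
            "tree_height_m": [s.tree_height for s in db.entries],
            "canopy_width_m": [s.canopy_width for s in db.entries],
            "lai": [s.leaf_area_index for s in db.entries],
            "faunal_groups": [";".join(sorted(s.faunal_groups)) for s in db.entries],
            "services": [";".join(sorted(s.services)) for s in db.entries],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def shade_index(canopy_width: float, tree_height: float) -> float:
    """Shade index SI = CW × TH in m²; both arguments must be positive."""
    if not (canopy_width > 0 and tree_height > 0):
        raise ValidationError(
            f"shade_index needs positive CW and TH, got CW={canopy_width}, TH={tree_height}"
        )
    return canopy_width * tree_height


def carbon_value(tree_height: float, db: TraitDatabase) -> str:
    """Carbon tier from height tertiles of the database.

    Low if TH ≤ P33, Medium if P33 < TH ≤ P66, High if TH > P66, with
    percentiles computed by linear interpolation over the database heights.
    """
    heights = {s.tree_height for s in db.entries}
    if len(heights) < 2:
        raise DegenerateDistributionError(
            "carbon tertiles need >= 2 distinct heights in the database"
        )
    p33, p66 = db.height_tertiles
    if tree_height <= p33:
        return "Low"
    if tree_height <= p66:
        return "Medium"
    return "High"


def ecosystem_category(n_services: int) -> str:
    """Service-count category: 0–3 Low, 4–6 Moderate, ≥ 7 High.

    A count of 0 is outside the nominal 1–3 Low bin and is mapped to Low
    with a logged warning so sparse inputs never crash a report.
    """
    if not float(n_services).is_integer() or n_services < 0:
        raise ValidationError(f"service count must be a non-negative integer, got {n_services}")
    n = int(n_services)
    if n == 0:
        logger.warning("species with 0 listed ecosystem services; categorized Low")
    if n <= 3:
        return "Low"
    if n <= 6:
        return "Moderate"
    return "High"


def faunal_score(groups) -> int:
    """Faunal biodiversity score: number of supported faunal groups (0–5)."""
    groups = frozenset(groups)
    unknown = groups - FAUNAL_GROUPS
    if unknown:
        raise ValidationError(f"unknown faunal group(s): {sorted(unknown)}")
    return len(groups)


def _normalize(value: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if hi == lo:
        return 0.5  # constant column contributes its mid-weight
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))


def cooling_index(
    tree_height: float, canopy_width: float, leaf_area_index: float, db: TraitDatabase
) -> float:
    """Cooling index CI in °C: 2 + 6·(0.4·TH_n + 0.2·CW_n + 0.4·LAI_n).

    Traits are min–max-normalized over the database bounds (values outside
    are clamped), so CI always lies in [2, 8].
    """
    if len(db) == 0:
        raise ValidationError("cooling_index needs a non-empty trait database")
    th_n = _normalize(tree_height, db.trait_bounds["tree_height"])
    cw_n = _normalize(canopy_width, db.trait_bounds["canopy_width"])
    lai_n = _normalize(leaf_area_index, db.trait_bounds["leaf_area_index"])
    w_th, w_cw, w_lai = CI_WEIGHTS
    return CI_MIN + (CI_MAX - CI_MIN) * (w_th * th_n + w_cw * cw_n + w_lai * lai_n)


def derive_scores(species: SpeciesTrait | str, db: TraitDatabase) -> DerivedScores:
    """All five derived scores for one database species, bundled."""
    sp = db.get(species) if isinstance(species, str) else db.get(species.name)
    return DerivedScores(
        shade_index=shade_index(sp.canopy_width, sp.tree_height),
        carbon_value=carbon_value(sp.tree_height, db),
        ecosystem_category=ecosystem_category(len(sp.services)),
        faunal_score=faunal_score(sp.faunal_groups),
        cooling_index=cooling_index(sp.tree_height, sp.canopy_width, sp.leaf_area_index, db),
    )
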