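"""Stand-level dashboard metrics for a planting layout.

Covers the 10:20:30 species-diversity rule (no species above 10% of the
stand, no genus above 20%, no family above 30%), Pielou's evenness
J = H / ln S (Shannon entropy of species proportions over the number of
species present; J = 0 for a monoculture), the connectivity index (fraction
of tree pairs within a geodesic threshold, default 50 m), and a combined
Low/Moderate/High biodiversity category.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .placement import PlantingLayout, haversine
from .traits import TraitDatabase

#: 10:20:30 rule thresholds as fractions, per taxonomic level.
RULE_THRESHOLDS = {"species": 0.10, "genus": 0.20, "family": 0.30}

CONNECTIVITY_THRESHOLD_M = 50.0

#: evenness above which a rule-compliant stand is classed High.
EVENNESS_HIGH = 0.8


@dataclass
class RuleReport:
    max_species_share: float
    max_genus_share: float
    max_family_share: float
    passes: bool
    violations: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class ScoreReport:
    rule: RuleReport
    evenness: float
    connectivity: float
    biodiversity_category: str
    species_counts: dict[str, int]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _shares(labels: list[str]) -> dict[str, float]:
    total = len(labels)
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0 / total
    return out


def richness_rule(layout: PlantingLayout, db: TraitDatabase) -> RuleReport:
    """Audit a layout against the 10:20:30 rule.

    Shares are counts over the stand total at species, genus and family
    level; a share exactly at its threshold passes (≤, not <). An empty
    layout passes trivially with all shares 0.
    """
    if len(layout) == 0:
        return RuleReport(0.0, 0.0, 0.0, passes=True)
    species = [t.species for t in layout]
    genera = [db.get(t.species).genus for t in layout]
    families = [db.get(t.species).family for t in layout]
    violations: list[tuple[str, str, float]] = []
    maxima = {}
    for level, labels in (("species", species), ("genus", genera), ("family", families)):
        shares = _shares(labels)
        maxima[level] = max(shares.values())
        for taxon, share in sorted(shares.items()):
            if share > RULE_THRESHOLDS[level] + 1e-12:
                violations.append((level, taxon, share))
    return RuleReport(
        max_species_share=maxima["species"],
        max_genus_share=maxima["genus"],
        max_family_share=maxima["family"],
        passes=not violations,
        violations=violations,
    )


def pielou_evenness(counts) -> float:
    """Pielou's evenness J = H / ln S over species with positive counts.

    H is Shannon entropy (natural log) of the count proportions and S the
    number of species present. A stand with a single species (S ≤ 1) has
    maximal dominance and is assigned J = 0.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size and (counts < 0).any():
        raise ValidationError("species counts must be non-negative")
    counts = counts[counts > 0]
    total = counts.sum()
    if total < 1:
        raise ValidationError("evenness needs at least one tree")
    s = counts.size
    if s <= 1:
        return 0.0
    if np.all(counts == counts[0]):
        return 1.0  # perfectly even stand; avoid float residue in H/ln S
    p = counts / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(s)


def connectivity_index(layout: PlantingLayout, threshold: float = CONNECTIVITY_THRESHOLD_M) -> float:
    """Fraction of tree pairs within ``threshold`` meters (inclusive).

    With fewer than two trees there are no pairs and no cohesion: 0.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    n = len(layout)
    if n < 2:
        return 0.0
    connected = sum(
        1
        for a, b in combinations(layout.trees, 2)
        if haversine(a.location, b.location) <= threshold
    )
    return connected / (n * (n - 1) / 2)


def biodiversity_category(
    rule: RuleReport, evenness: float, evenness_high: float = EVENNESS_HIGH
) -> str:
    """Combine rule compliance and evenness into Low/Moderate/High.

    High needs both rule compliance and J ≥ ``evenness_high``; exactly one
    of the two gives Moderate; neither gives Low.
    """
    good = int(rule.passes) + int(evenness >= evenness_high)
    return {2: "High", 1: "Moderate", 0: "Low"}[good]


def score_report(
    layout: PlantingLayout,
    db: TraitDatabase,
    connectivity_threshold: float = CONNECTIVITY_THRESHOLD_M,
) -> ScoreReport:
    """Recompute every stand metric from scratch (stateless).

    An empty layout yields J = 0, connectivity 0 and a trivially passing
    rule rather than an error, so dashboards never crash on a blank map.
    """
    rule = richness_rule(layout, db)
    counts = layout.species_counts()
    evenness = pielou_evenness(counts.values()) if counts else 0.0
    return ScoreReport(
        rule=rule,
        evenness=evenness,
        connectivity=connectivity_index(layout, connectivity_threshold),
        biodiversity_category=biodiversity_category(rule, evenness),
        species_counts=counts,
    )
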