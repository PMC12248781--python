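"""Derive the per-species ecological scores from a trait database.

Builds a small synthetic species database and prints every derived score
for one species: shade index (m², canopy width x height), carbon tier
(height tertiles), ecosystem-service category (service count), faunal
score (supported groups, 0-5) and cooling index (2-8 °C from weighted
normalized traits).
"""

import treegrid as tg

db = tg.gen_species_db(tg.SynthConfig(seed=42, n_species=20))
sp = db.entries[0]
scores = tg.derive_scores(sp.name, db)

print(f"species          : {sp.name} ({sp.genus}, {sp.family})")
print(f"traits           : TH={sp.tree_height:.1f} m  CW={sp.canopy_width:.1f} m  LAI={sp.leaf_area_index:.1f}")
print(f"shade index      : {scores.shade_index:.1f} m^2   (CW x TH; larger = more lateral shading)")
print(f"carbon value     : {scores.carbon_value}   (height tertile; taller trees store more carbon)")
print(f"ecosystem svcs   : {scores.ecosystem_category}   ({len(sp.services)} services; 1-3 Low, 4-6 Moderate, 7+ High)")
print(f"faunal score     : {scores.faunal_score}/5   (groups: {', '.join(sorted(sp.faunal_groups)) or 'none'})")
print(f"cooling index    : {scores.cooling_index:.2f} degC   (expected local canopy cooling, 2-8 degC scale)")
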