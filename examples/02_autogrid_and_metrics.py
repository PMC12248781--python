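"""Fill a planning polygon with Autogrid and score the resulting stand.

Autogrid lays a deterministic grid over the polygon (spacing = largest
requested canopy width) and serves species round-robin so no two canopies
overlap. The stand report combines the 10:20:30 diversity rule, Pielou
evenness, and the 50 m connectivity index.
"""

import treegrid as tg

db = tg.gen_species_db(tg.SynthConfig(seed=42, n_species=20))
poly = tg.square_polygon(30.3, 78.0, 1500.0)  # 1.5 km square near Dehradun latitudes

requests = [(s.name, 4) for s in db.entries[:5]]  # 4 trees of each of 5 species
layout, fill = tg.autogrid(poly, requests, db)
print(f"placed {len(layout)} trees; request fully satisfied: {fill.complete}")

report = tg.score_report(layout, db)
print(f"max species share  : {report.rule.max_species_share:.0%} (rule passes: {report.rule.passes})")
print(f"Pielou evenness J  : {report.evenness:.3f}   (1.0 = perfectly even species mix)")
print(f"connectivity index : {report.connectivity:.3f}   (fraction of tree pairs within 50 m)")
print(f"biodiversity score : {report.biodiversity_category}")
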