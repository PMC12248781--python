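# treegrid

A headless planning engine for biodiversity-oriented urban tree planting,
aimed at urban foresters, spatial ecologists and planning tool builders. It
covers the full desk workflow: score candidate species from their traits,
place trees on a map without canopy conflicts (manually or automatically),
audit the stand's diversity and spatial cohesion, simulate the local
land-surface-temperature (LST) reduction under the canopies, and predict
bird-habitat suitability over the landscape with a small neural network.
Everything runs on seeded synthetic inputs, so results are reproducible
end to end without any external data.

## The models

**Per-species scores.** From maximum tree height TH (m), maximum canopy
width CW (m) and leaf area index LAI:

- Shade index `SI = CW × TH` (m²);
- Carbon tier: Low/Medium/High by the 33rd/66th percentiles of database heights;
- Ecosystem-service category: 1–3 services Low, 4–6 Moderate, 7+ High;
- Faunal score: number of supported groups among pollinators, birds,
  insects, lizards, mammals (0–5);
- Cooling index `CI = 2 + 6·(0.4·TH_n + 0.2·CW_n + 0.4·LAI_n)` (°C), with
  each trait min–max-normalized over the database, so CI spans 2–8 °C.

**Stand metrics.** The 10:20:30 rule (no species > 10%, genus > 20%, family
> 30% of the stand), Pielou's evenness `J = H / ln S` (Shannon entropy of
species proportions), and a connectivity index: the fraction of tree pairs
within 50 m great-circle (haversine) distance.

**Placement.** Trees carry a canopy buffer of radius CW/2; conflicts are
detected geodesically. Autogrid deterministically fills a polygon from a
grid spaced by the largest requested canopy, serving species round-robin.

**Cooling simulation.** Each tree subtracts its species CI from the raster
pixels whose centers its buffer covers; overlapping buffers take the
maximum CI.

**Habitat model.** A 5→16→8→1 ReLU/sigmoid MLP trained with Adam on binary
cross-entropy (150 epochs, batch 10, 80:20 split, all randomness seeded)
predicts bird presence from (LST, CI, SI, height, diameter); prediction over
a raster mean-fills the non-LST features, and pixels with probability > 0.5
are habitat hotspots. Discrimination is reported as rank-based (Mann–Whitney)
AUC.

## Worked example

```sh
python examples/02_autogrid_and_metrics.py
```

```
placed 20 trees; request fully satisfied: True
max species share  : 20% (rule passes: False)
Pielou evenness J  : 1.000   (1.0 = perfectly even species mix)
connectivity index : 0.195   (fraction of tree pairs within 50 m)
biodiversity score : Moderate
```

Twenty trees — four each of five species — were placed conflict-free in a
1.5 km square. Equal counts give perfect evenness (J = 1.0), but with only
five species each one holds 20% of the stand, so the 10:20:30 rule fails
and the combined biodiversity score is Moderate; about a fifth of all tree
pairs sit within 50 m of each other. The other examples
(`01_species_scores.py`, `03_cooling_simulation.py`, `04_habitat_model.py`)
walk the scoring, cooling and habitat pipelines the same way.

The same workflows are available from the shell:

```sh
treegrid gen-fixtures --seed 7 --out-dir fixtures/
treegrid score --layout fixtures/layout.csv --traits fixtures/db.csv
treegrid simulate-cool --lst fixtures/lst.tif --layout fixtures/layout.csv --out cooled.tif
treegrid train-habitat --layout fixtures/layout.csv --traits fixtures/db.csv \
    --lst fixtures/lst.tif --seed 7 --out model.json
treegrid predict-habitat --model model.json --lst fixtures/lst.tif --out prob.tif --hotspots hot.tif
```

## Formats

- Trait CSV: `species, genus, family, tree_height_m, canopy_width_m, lai,
  faunal_groups, services` (semicolon-separated lists).
- Layout CSV: `species, latitude, longitude, size_m, cooling_index`
  (WGS84 decimal degrees, meters, °C).
- Rasters: single-band WGS84 GeoTIFF (or plain-text ESRI ASCII `.asc`).
- Polygons: GeoJSON (lon/lat order).
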