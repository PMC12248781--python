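# Methods

## Species scoring

Each species is described by three morphological traits — maximum tree
height TH (m), maximum canopy width CW (m) and leaf area index LAI — plus
the faunal groups it supports and the ecosystem services it provides.

**Shade index.** `SI = CW × TH` in m², a first-order proxy for lateral
canopy shading. With the synthetic trait ranges below its attainable
maximum is 25 m × 35 m = 875 m².

**Carbon tier.** TH is cut at the 33rd and 66th percentiles of the loaded
database's height distribution (linear-interpolation percentiles). A height
exactly at a boundary goes to the lower tier (≤ P33 → Low); taller trees
are assumed to store more carbon. At least two distinct heights are
required, otherwise the tertiles are undefined and an error is raised.

**Ecosystem-service category.** 1–3 services Low, 4–6 Moderate, ≥ 7 High.
The ≥ 7 reading makes the bins exhaustive (a strict > 7 would leave a count
of exactly 7 uncategorized). A count of 0 falls outside the nominal bins
and is mapped to Low with a logged warning rather than an error, so sparse
databases never crash a report.

**Faunal score.** The cardinality of the supported-groups set over
{pollinators, birds, insects, lizards, mammals}, hence an integer 0–5. Any
finer weighting of food/shelter/habitat value per group would need data the
trait table does not carry.

**Cooling index.** The plausible local cooling of a mature urban canopy,
scaled to 2–8 °C:

    CI = 2 + 6 · (0.4·TH_n + 0.2·CW_n + 0.4·LAI_n)

Height and leaf area dominate (40% each) because they drive shading volume
and evapotranspiration; canopy width contributes the remaining 20%. Each
trait is min–max-normalized over the loaded database; values outside the
database bounds are clamped to [0, 1], and a constant trait column
normalizes to 0.5 so it contributes exactly its mid-weight instead of
producing a 0/0. The weights sum to 1, so CI is bounded by [2, 8] for every
input — a property the test suite asserts over random databases.

Normalizing against the *loaded database* means CI is relative to the
species pool under consideration, not an absolute physical prediction; the
same species can score differently in different pools. That is the intended
dashboard semantics (ranking a candidate list), not a microclimate model.

## Geometry and placement

Distances are great-circle (haversine) on a sphere of radius 6,371,000 m —
the convention of the common geospatial libraries; the suite checks the
closed forms (1° of meridian = R·π/180) and agreement with the planar
approximation to 0.1% below 100 m separation. Polygon membership is
even–odd in the lon/lat plane with boundary points counted inside
(delegated to shapely).

A planted tree's canopy buffer is the circle of radius diameter/2 = CW/2
around its stem. Two conflict rules: *point-in-buffer* (a proposed stem
falls strictly inside an existing buffer) and *canopy-overlap* (stem
distance strictly below the sum of the two radii). Manual placement warns
but does not block by default (`strict=False`), mirroring interactive use;
`strict=True` raises and leaves the layout unchanged.

**Autogrid** is fully deterministic, with no randomness to seed:

1. grid spacing = the largest requested species' CW, which guarantees
   same-species grid neighbors can never overlap;
2. candidates are grid nodes over the polygon's bounding box whose centers
   fall inside the polygon, traversed row-major from the north-west corner
   (longitude spacing uses the cosine of the bounding box's mid-latitude);
3. species are served round-robin, ordered by CW descending (largest first
   maximizes feasibility), one tree per pending species per cycle, each at
   the first candidate passing the canopy-overlap audit against every tree
   already placed;
4. the fill stops when requests are met or no candidate fits; the report
   carries per-species placed/requested counts and the shortfall.

A canopy may overhang the polygon edge: membership is by stem position
only, matching how a user clicks a point on a map. Every Autogrid output
is audited in the tests against an O(n²) pairwise-overlap oracle.

## Stand metrics

- **10:20:30 rule**: maximum share per species ≤ 10%, per genus ≤ 20%, per
  family ≤ 30%; a share exactly at a threshold passes. Taxonomy comes from
  the trait database, never inferred from names.
- **Pielou evenness**: J = H/ln S with natural-log Shannon entropy over
  species with positive counts. S ≤ 1 is the 0/0 case and is defined as
  J = 0 (maximal dominance). Exactly equal counts return 1.0 exactly
  rather than accumulating float residue.
- **Connectivity index**: connected pairs (haversine ≤ 50 m, inclusive)
  over all C(n, 2) pairs; fewer than two trees → 0 (no pairs, no
  cohesion). The 50 m default approximates a faunal movement-corridor
  scale and is a parameter.
- **Biodiversity category**: High iff the rule passes *and* J ≥ 0.8;
  exactly one of the two → Moderate; neither → Low. The 0.8 cutoff and the
  AND logic are this package's own convention (both inputs are reported
  alongside it, and the cutoff is configurable).

## Cooling simulation

The LST raster is north-up WGS84 with square degree pixels; no-data is NaN
in memory. A pixel is under a buffer when its *center* is within
diameter/2 geodesic distance of the stem (standard center-in-circle
rasterization). Per pixel the applied reduction is the **maximum** cooling
index over covering trees — summing would exceed the 2–8 °C species range
wherever two canopies overlap, which is physically implausible shading
twice over. `modified = original − delta` everywhere; no-data pixels are
untouched and excluded from the covered-pixel count. The CI is applied
uniformly across the buffer with no radial falloff; attenuation toward the
canopy edge would need a within-canopy model the trait data cannot support.
At 30 m pixels, canopies narrower than ~15 m may cover no pixel center at
all — their cooling is simply sub-grid.

GeoTIFF I/O goes through tifffile, writing the ModelPixelScale,
ModelTiepoint, GeoKeyDirectory (EPSG 4326) and GDAL no-data tags, and is
bit-exact on round trip; the ESRI ASCII `.asc` path exists for plain-text
fixtures (values kept to float32 precision).

## Habitat model

One training sample per planted tree: features (LST at the tree's pixel,
CI, SI, TH, canopy diameter), label 1 iff the species supports birds.
Trees off-raster or on no-data pixels are dropped with a warning.

The network is 5 → h1 → h2 → 1 with ReLU hidden activations and a sigmoid
output; defaults h1, h2 = 16, 8 — small enough to fit tens of samples
without memorizing, large enough for the nonlinear interactions. Training
is mini-batch Adam (rate 0.001, β₁ = 0.9, β₂ = 0.999) on binary
cross-entropy for 150 epochs at batch size 10 with an 80:20
train:validation split. Determinism: one seeded generator drives the split
shuffle, the per-epoch batch order and the Glorot-uniform weight
initialization, so identical inputs and seed give bit-identical weights
and history. Features are z-score standardized with *training-split*
statistics only; the tests verify that perturbing validation-side samples
never moves the normalizer (no leakage). Accuracy is the fraction correct
at a 0.5 cutoff.

Raster prediction builds each pixel's feature vector from its LST plus the
raw training means of the other four features (means are filled first,
then standardized), so the surface varies with temperature alone; no-data
propagates. Hotspots are pixels with probability strictly above 0.5 — a
pixel at exactly 0.5 is not a hotspot.

AUC is the rank (Mann–Whitney) statistic with mid-rank ties; the ROC curve
sweeps every distinct score as a threshold. The tests cross-check the rank
AUC against trapezoidal integration of the curve (≤ 1e-9) and against
scikit-learn's independent implementation.

## Synthetic data

The generators stand in for a regional species database and a satellite
LST product:

- **Species**: TH ~ U(5, 35) m, CW ~ U(3, 25) m, LAI ~ U(1, 9) —
  envelopes of common North-Indian-plains urban trees, chosen so SI spans
  up to 875 m² and CI its full 2–8 °C scale; birds are supported with
  probability `bird_prob` (default 0.5) and the other four groups with
  probability 0.5 each; 1–9 services are drawn from the nine-item
  catalogue; genera hold about two species and families about two genera,
  so 10:20:30-compliant layouts are constructible.
- **LST raster**: default 64×64 pixels of 0.00027° (~30 m at the equator),
  a radial urban-heat-island ramp from 44 °C at the center to 28 °C at the
  edges plus Gaussian noise (σ = 2% of the range), clipped to the range.
- **Layouts**: conflict-free rejection sampling inside a polygon with
  uniformly drawn species, bounded attempts, deterministic per seed.

What the generators deliberately omit: trait covariance (real height and
canopy width correlate), spatial autocorrelation of land cover beyond the
single radial gradient, any ecological association between temperature and
bird presence, and cloud/no-data structure. Passing tests therefore
demonstrate the *mechanics* — scoring, placement, rasterization, training,
evaluation — under controlled conditions, not ecological validity on real
survey data; on real data the habitat model's discrimination depends
entirely on how informative the five features are.

## Numerical choices and problem sizes

- Haversine clamps its argument into asin's domain to survive rounding at
  antipodal points; Earth radius 6,371,000 m.
- Rule shares are compared with a 1e-12 slack so a count of exactly 10 in
  100 passes despite binary fractions.
- CSVs are written at 17 significant digits and read with pandas'
  round-trip float parser, making layout and trait files lossless.
- Test and demonstration workloads are kept small — databases of ~20
  species, stands of tens of trees, rasters of 48–64 pixels per side, and
  training runs of 150 epochs on ≤ 400 samples — sizes at which every
  check, including the O(n²) placement and ROC oracles, completes in
  seconds while still exercising each code path.

## Known limitations

- Cooling is a dashboard simulation, not microclimate physics: no
  advection, seasonality, or canopy-density dynamics.
- CI's database-relative normalization makes scores pool-dependent.
- The habitat label derives from species traits, so at the stand level it
  is deterministic per species; real presence data would add observation
  noise and site effects the model currently never sees.
- Autogrid optimizes nothing: it is a deterministic fill chosen for
  reproducibility and evenness, not a packing or utility optimizer.
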