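# Methods

## The model

`coastvuln` implements a relative, index-based assessment of coastal
vulnerability for a region sampled as shoreline points at fixed spacing
(1 km by default) in a projected planar coordinate system.

**Index of exposure (IE).** Six biophysical variables are ranked 1 (very
low exposure) to 5 (very high) and combined as a geometric mean:

    IE = (R_relief · R_waves · R_wind · R_surge · R_habitats · R_change)^(1/6)

- *Relief* (m) and *wave exposure* use fixed class boundaries
  (relief: 0–2 → 5, 2–4 → 4, 4–8 → 3, 8–12 → 2, ≥ 12 → 1; waves:
  < 0.75 → 1, 0.75–3 → 2, 3–18.75 → 3, 18.75–48 → 4, ≥ 48 → 5).  The
  published wave-row limits contain a tiny discontinuity (18.70 vs 18.75);
  contiguous edges [0.75, 3, 18.75, 48] are used so every value is ranked.
  Intervals are closed at the lower edge, open at the upper; out-of-range
  values clamp to the extreme class on that side.  The interval-closure
  convention is a package choice — the source method does not state one.
- *Wind exposure* and *surge potential* (distance to the 30-m depth
  contour) are ranked by region-wide quintiles: breakpoints at the
  20/40/60/80th percentiles (linear-interpolation definition), ties going
  to the lower class, so a constant field collapses to rank 1.  Quintiles
  are computed over the pooled analysis region in one pass, not per
  country, because the assessment is a supra-national comparison.
- *Natural habitats*: coral reef and mangrove carry protection rank 1,
  seagrass rank 4, no habitat within reach 5.  A habitat protects a
  shoreline point when any of its polygons lies within the class's
  protective distance; when several classes are in reach the minimum rank
  (most protective) wins.  Default protective distances — coral 2,000 m,
  mangrove 1,000 m, seagrass 500 m — are explicit working assumptions
  (configurable); the combination-by-minimum rule is likewise the package's
  own, chosen as the simplest defensible rule rather than any specific
  multi-habitat attenuation formula.
- *Shoreline change rate* (m/yr): > +2 → 1, (+1,+2] → 2, [−1,+1] → 3,
  [−2,−1) → 4, < −2 → 5.  Rates exist only for sandy shores; missing
  rates take a configurable neutral default of 3 to avoid biasing
  non-sandy coasts toward either extreme.
- Sea-level-change rates are deliberately not an input.

The continuous IE is collapsed to classes 1–5 by nearest-integer rounding
(halves up), so "higher exposure" (H, classes 4–5) means IE ≥ 3.5; the
rule is configurable to quintile classing.  Rounding was chosen because
reported regional H fractions are far from the 40% a pure quintile rule
would force.

**Habitat scenarios.** S1 keeps all three habitat classes ("current
conditions"); S2–S4 drop corals, mangroves, seagrasses respectively; S5
drops all (R_habitats = 5 everywhere).  Only the habitat rank is
recomputed across scenarios, so removing a habitat class can never lower
any point's IE (scenario monotonicity; asserted in tests).

**Population at higher exposure.** People in grid cells whose centres lie
within 5 km (configurable) of at least one H point, each cell counted
once (union semantics).  Aggregation applies the union within each
administrative unit at each level, so district figures may sum to more
than their province's.  Cell membership is by centre, not area-weighted
overlap, for determinism.

**Social vulnerability index (SVI).** Eight district census indicators
(% population < 4, % > 65, % annual growth, density/km², % illiterate,
% natural-material housing, % unimproved water, % unimproved waste) are
transformed ln(v+1), z-scored across included districts (sample sd, n−1),
summed with direction weights (+1 for all eight by default), and ranked
1–5 by the same quintile rule as above.  The +1 offset admits zero-valued
percentages and is configurable (0 for strictly positive data).  Districts
with incomplete census records are excluded, not imputed.  Standardisation
is pooled across countries (configurable) since the comparison is
cross-country.

**IVCC.** At district level, IVCC = SVI rank + mean point IE within the
district; at province level, the mean of district SVI ranks (ranks, not
raw scores — reported province values such as 4.6 are only reachable this
way) plus the mean IE over all province points (point-weighted, not a mean
of district means).  Range [2, 10].  Districts with IVCC > 7 (strict) are
*areas of priority concern*; those additionally with > 90% (strict) of
coastline at H under S1 are *critical areas*.  Units without census data
carry no SVI/IVCC and are reported as excluded.

**Validation.** Districts split into exposed/less-exposed at thresholds of
20/25/30/50% of shoreline points at H under S1 (inclusive ≥).  Two-sided
Mann-Whitney U tests compare hazard-event counts and fatal-event counts
between groups (exact enumeration when n_a·n_b ≤ 20 and untied, otherwise
tie-corrected normal approximation with continuity correction — the
behaviour of common statistics packages); Spearman rank correlations
(midrank, tie-safe; t-approximation p-values) relate %-at-H and IVCC to
the counts.  α is left to the caller; two-sided p-values are reported.

## Synthetic data

`RegionSpec`/`generate_region` produce complete seeded regions:

- Coastline: x advances monotonically while y follows moving-average
  smoothed noise (amplitude 3 km, correlation length 25 km); points at
  1-km arc spacing.
- Fields: lognormal transforms of smoothed standard noise — relief median
  ≈ 3.3 m, wave power median ≈ 7.4 spanning the full ranking range, wind
  and shelf distance likewise positive and autocorrelated.
- Shoreline-change rates exist on contiguous "sandy" runs (~50% of the
  coast, mean alternation cycle 30 km), mimicking real beach stretches
  rather than i.i.d. gaps.
- Habitat ribbons buffer random along-coast sub-segments; default
  coverage fractions (mangrove 0.60, coral 0.34, seagrass 0.08) follow
  the regional shares of coastline each habitat protects in the East
  African setting.  Empirical coverage lands within ±0.1 of the target
  for coasts ≥ 500 km (tested).
- Population: total 2 million spread over a 1-km grid with
  exp(−d/5 km) decay from the coast times lognormal noise.
- Census: the eight indicators are correlated lognormal draws
  (inter-indicator correlation 0.5) with medians near regional averages
  (e.g. housing 60%, unimproved water 40%, waste 55%).
- Events: district counts ~ Poisson(exp(0.5 + 2·pctH/100)) where pctH is
  the district's true % of points at H under S1; fatal events are a
  Binomial(0.4) thinning, guaranteeing n_fatal ≤ n_events.

What the generator does **not** emulate: real bathymetry-driven wave/surge
physics, habitat condition or fragmentation, dasymetric population
detail, census measurement error, or reporting biases in disaster
inventories.  Passing tests therefore demonstrate the pipeline's
arithmetic, its invariants and its statistical calibration — not that any
particular real coastline would receive these rankings.

`regional_summary_fixture` expands the published regional summary's printed point
counts (22,112 points, 4,827 at H with habitats, 8,603 without, and the
per-country/province rows) into point tables, so the summarization and
reporting path can recompute the printed percentages and differences
exactly; it contains no geometry and is used only by worked-example tests
and the acceptance script.

## Numerical choices

- Boundary points between district polygons attribute to the smaller
  unit_id (deterministic tie-break; the convention, not derived from any
  source).
- Coastline statistics are point counts × spacing, matching point-based
  reporting; partition conservation (district → province → country →
  region) then holds exactly.
- Reported percentages and indices round half-up to one decimal (so
  100·2620/10237 → 25.6); CSVs keep full precision.
- Geometric-mean identity exp(mean(ln r)) holds to 1e-12 in tests; IE is
  bounded by the min/max rank and permutation-invariant.
- Degenerate inputs: constant quantile input → all rank 1; zero-variance
  Spearman input → rho undefined (NaN, logged); validation groups of one
  still run the U test; empty H point sets give zero population.

## Problem sizes used in tests and the acceptance run

The shared test region uses a 300-km coast (~450 points, 12 districts);
habitat-coverage and acceptance synthetic runs use 600 km (~1,000
points).  Validation calibration/power checks run 200 replicates of 100
districts through the event model at the district-summary level — the
same model `generate_region` uses — which keeps the statistical tests
tight while the full geometric pipeline is exercised once per suite.

## Known limitations

- Protective distances and the habitat combination rule are assumptions;
  results are sensitive to them where habitats are sparse.
- The IE→class rounding rule is a choice; quintile classing is available
  but changes H fractions materially.
- Indices are relative to the analysed region only; they say nothing
  about absolute hazard and nothing about change through time.
- The population grid interface reads ESRI ASCII only; GeoTIFF inputs
  must be converted upstream.
- Coordinates must arrive projected (planar metres); no reprojection is
  performed.
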