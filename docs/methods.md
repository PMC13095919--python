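# Methods

This note records the models, conventions and design choices behind
`heatregions`, in the spirit of a statistical package's methods
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Thermal index

Apparent temperature (AT) is the "feels-like" exposure metric pairing
maximum air temperature with humidity. Two variants are implemented:

- **Dew-point quadratic (default).**
  `AT = −2.653 + 0.994·Ta + 0.0153·Td²` (°C), the form standard in
  California heat-health studies. It is affine in `Ta` at fixed dew point
  and even, quadratic and non-decreasing in `|Td|`.
- **Vapor-pressure form.** `AT = −1.3 + 0.92·Ta + 2.2·e` with `e` the
  vapor pressure (kPa) at the dew point, available behind
  `variant="vapor_pressure"` because reanalysis products differ in which
  humidity variable they deliver.

Relative humidity is bridged to dew point with the Magnus approximation
(`a = 17.625`, `b = 243.04 °C`): `γ = a·t/(b+t) + ln(rh/100)`,
`Td = b·γ/(a−γ)`. At saturation `Td = t` exactly; the tests also check the
closed form against a numerical inversion of the saturation-vapor-pressure
ratio. Dew points more than 0.5 °C above the day's maximum temperature are
rejected as physically inconsistent.

Monthly means are plain arithmetic means per unit-month. The strict
missing-data policy (default) raises on gaps — a silently short month would
bias the mean the pair tests consume; a lenient NA-skipping policy is
available. °C→°F conversion is the exact affine map, applied after
aggregation (the two commute, which is tested).

## Two-stage clustering

Columns (days) are standardized to zero mean and unit sample variance
(ddof = 1); zero-variance columns carry no contrast and are dropped with a
warning. PCA is computed by SVD of the standardized matrix, which is
algebraically the eigendecomposition of the correlation matrix; components
with eigenvalue above 1.0 are retained (Kaiser rule; the threshold is
configurable). Loading signs are fixed so each component's
largest-magnitude loading is positive, making reruns bit-stable.

k-means is Lloyd's algorithm, squared-Euclidean, best of `n_starts = 25`
random initializations (k distinct observations each), `max_iter = 300`.
An empty cluster is repaired by reseeding its centroid at the point
farthest from its current centroid; nearest-centroid ties break to the
lowest cluster index. All randomness flows from a single seed.

The number of clusters is chosen by a plurality vote of validity indices —
silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, and the gap statistic
by default, extensible via config — emulating a many-index ensemble vote
with a small documented set. Ties resolve to the smallest k. When the
candidate range includes k = 1 (stage 2), the gap statistic with uniform
reference nulls (default 50 replicates, seeded; one-standard-error rule)
first decides whether any partition beats a single cluster, because the
partition indices are undefined at k = 1.

Degenerate-case conventions, needed because noise-free planted data makes
whole clusters coincide at a point: a singleton's silhouette is 0, as is a
point whose within- and between-distances both vanish; an unbounded Dunn
ratio is capped at 10⁶; non-finite Calinski–Harabasz/Davies–Bouldin values
count as worst-possible in the vote; within-dispersions are floored at
10⁻¹² before taking logs in the gap statistic.

Stage 2 reruns the *entire* procedure — standardization, PCA, k-selection,
k-means — on the raw series of each stage-1 cluster's members, rather than
slicing stage-1 scores: the within-cluster correlation structure differs
from the global one. Clusters with fewer than two cells, or whose member
series are identical (no contrast after standardization), are forced to a
single leaf. Composite labels are `"s1.s2"` with 1-based stage indices.

### Recovery-fixture design

The planted hierarchical fixture is a 6×6 grid of three vertical
super-strips (baselines 10 °C apart) each split into two sub-profiles
(2 °C apart), so "day noise at 10% of the profile separation" is
σ_day = 0.2 °C. The stage ranges for this fixture are (2, 3) and (1, 3)
rather than the paper-scale defaults (10–20, 1–10): with zero noise every
planted leaf collapses to a single point in series space, and any k that
splits leaves further scores perfect internal indices (a coincident
sub-blob has silhouette 1), so a range bracketing the true super-cluster
count is the honest analogue of fixing the candidate range a priori at
full scale. Recovery is asserted as adjusted Rand index 1 (noise-free)
and ≥ 0.9 across 10 seeds (noisy).

## Spatial delineation and population

Thiessen cells are built with shapely's Voronoi diagram on an envelope
comfortably larger than the boundary, matched back to their generators,
and clipped; the clipped result is independent of the envelope size. A
brute-force nearest-generator check on a dense sample grid backs this in
the tests. Duplicate generators and generators outside the boundary are
rejected. Same-label cells are dissolved by unary union; the fragment
inventory orders disjoint parts by descending area (ties by original part
order), so `fragments[0]` is the "main" part.

Population handling follows the dasymetric convention: pixel membership is
by pixel-center-in-polygon (boundary inclusive) — at a 100:1 scale gap
between the population raster and the climate grid, partial-pixel error is
negligible and the simpler rule keeps totals exactly additive. The
population-weighted centroid is the value-weighted mean of member pixel
centers; a zero-population polygon falls back to its geometric centroid
and is flagged. Zip units are assigned to the region covering their
weighted centroid; a centroid exactly on a shared edge goes to the
lexicographically smallest region id, and a centroid outside every region
(numeric edge case) to the nearest region, logged. Region populations are
group sums over assigned zips, with empty regions retained at 0.

The synthetic population raster carries integer person counts apportioned
by largest remainder, so pixel sums equal the requested total exactly and
the end-to-end conservation checks can demand exact equality rather than a
float tolerance.

## Consolidation

The exact Wilcoxon signed-rank test drops zero differences, midranks tied
magnitudes, and enumerates the full sign-pattern null by convolution over
(doubled) ranks; the two-sided p doubles the smaller tail, capped at 1.
Above 20 nonzero differences it falls back to the tie-corrected normal
approximation with continuity correction (logged); an all-zero input is
degenerate with p = 1 and a warning. Tests verify exact agreement with an
independent brute-force enumeration over 200 random inputs with ties and
zeros, and agreement with an established implementation on tie-free cases.
With five paired months, the smallest attainable two-sided p is
2/32 = 0.0625, attained by any uniformly signed five-vector — so at
α = 0.1 a uniformly warmer neighbor is always significantly different,
and merges happen only across mixed-sign (or zero-inflated) differences.

Eligibility is conjunctive by default — fragmented *and* population
strictly below the threshold (11,000 persons, or a percentile of region
populations resolved by linear interpolation) — with a disjunctive option.
Candidate partners are the regions adjacent to the source (per fragment
for multipart sources, so fragments can be routed to different targets);
partners must be non-significant at α and, when an elevation-style
covariate with tolerance τ is supplied, within τ of the source. Candidates
rank by smallest mean absolute monthly difference, ties by id. Other
eligible regions are excluded as targets, which keeps every plan acyclic
by construction. Sources with no admissible partner stay unmerged and are
flagged for review.

Applying a plan unions source geometries (whole or per original fragment
index) into their targets, re-assigns the affected zips against the new
geometry, conserves total area and population, and is idempotent.
Reported p-values are rounded to two decimals in output tables; full
precision is kept internally. Note the direction of the α gate: merging
requires p ≥ α, so *lowering* α admits more partners.

## Description

Temperature bands are half-open `[lo, hi)` in °F with edges at 60, 70, 75,
80, 85; the lowest band is open-ended below (a 49.5 °F region is still
"Coolest") and the highest above, making the scale total and monotone. The
modal category is reported, or both categories when the months span two
(ordered by frequency, then scale position); more than two distinct
categories report the two most frequent, logged. Locational labels are the
reference-layer names overlapping at least 25% of the *region's own* area,
in descending overlap order. The synthetic reference layer is a named 3×3
compass tiling of the boundary standing in for a coarse assessment-region
layer.

## Synthetic scenes and their limits

The generator plants rook-contiguous regions by seeded frontier growth and
gives each region a two-parameter seasonal profile: baseline plus a
half-sine ramp over the May 1 – Sep 30 window (153 days × 2 years = 306
values per cell; the window is fully configurable). Noise is a cell-level
offset (σ_cell) plus i.i.d. day noise (σ_day). Default scene: 16×12 cells
at 31 km, 12 regions with baselines spread over 12–36 °C and amplitudes
2–8 °C, σ_cell = 0.5 °C, σ_day = 1.5 °C, 120 Voronoi zips, and a
1,000,000-person clustered raster at 1/100 of the climate-cell side.

What the scenes do *not* emulate: spatially correlated weather noise,
orographic and coastal gradients within a region, non-sinusoidal seasonal
shapes, irregular grid clipping at a real coastline, and real zip-code
geometry. Passing tests therefore demonstrate the correctness of the
machinery and recoverability under the planted model, not climatological
realism; headline counts from the real study area (component counts,
cluster counts, region populations) are data-dependent and are not targets
of the synthetic runs.

## Numerical and reproducibility choices

One master seed fans out to the simulation, zip, population and clustering
stages by fixed offsets, so partial reruns are stage-reproducible; all
derived seeds stay below 2³¹. Exact stages rerun bit-identically; floating
stages to ~10⁻¹⁰. Problem sizes in the test and acceptance runs (6×6 and
8×6 grids, 30–120 zips, 10–20× raster refinement) are chosen so the whole
suite completes in minutes on a laptop-class single core while still
exercising every stage at full fidelity.
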