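# Methods

This note documents the models implemented in `seaplan`, the parameter
defaults and why they hold, the numerical choices made where the
procedure was genuinely open, what the synthetic data emulate, and the
known limitations.

## Vulnerability rubric

The rubric (`data/vulnerability_rubric.csv`) maps (statute, status,
trend, population class) to a score in {0.1, …, 0.8}; "small
population" means ≤ 500 individuals. It is a total function on its nine
rows and deliberately errors on anything else — silently defaulting a
protected species' vulnerability would be worse than failing loudly.

Two precedence decisions were required:

* **ESA Endangered + small population + non-improving trend → 0.1.**
  The most-vulnerable row covers "declining, small population, or
  both", so a small population dominates a stable or unknown trend.
* **ESA Endangered + small population + increasing trend → error.**
  The small-population row and the increasing-trend row (0.3) give
  contradictory answers and neither plausibly dominates; the rubric
  refuses rather than guesses. Users facing a genuinely recovering
  tiny population can add an explicit row to the CSV.

The rubric is monotone in trend (worsening trend never raises the
score) — this is enforced by a property test.

## Footprint derivations

* **Kernel density** uses a truncated quartic (biweight) kernel,
  K(d) = 3/(πr²)·(1 − (d/r)²)² for d < r, matching the GIS
  kernel-density convention; each point contributes unit mass, so the
  surface integrates to the point count (mass conservation is tested to
  ±0.5%). A truncated, renormalized Gaussian (σ = r/2) is available.
  The default density lattice is ¼ of the search radius per cell; the
  discretization error scales with that ratio, so tests use finer
  lattices where mass accuracy matters. Search-radius defaults: 19 km
  for telemetry and fishery-observer points, 40 km for aerial-survey
  points (wider to absorb transect spacing).
* **High-use areas** are the upper two quartiles of the
  positive-density cells: density ≥ median of positive cells, ties at
  the median included. Zero-density cells never enter the quantile
  computation — including the (dominant) zero background would make
  "the upper two quartiles" collapse to almost the whole positive
  support. With exactly two distinct positive values the interpolated
  median lies between them, so only the upper value class is selected;
  this follows from the ≥-median rule and is pinned by a test against
  the quantile oracle.
* **Volume contours** (default level 0.95) select cells greedily by
  descending density until the cumulative mass reaches the level — the
  smallest such region. A flat density across the cut is reported with
  a warning since the boundary is then arbitrary.
* **Residence buffers** default to 18.983 km, chosen so one isolated
  residence location becomes a ~1,132 km² disc, the mean published
  size of loggerhead 90/95% kernel home ranges. Buffers are
  discretized at 64 segments per quarter circle, keeping disc areas
  within 0.05% of πr².
* **Buffered hulls** (data-poor species): convex hull of all
  detections, buffered (default 30 km), then trimmed wherever depth
  exceeds the isobath cutoff (default 410 m). The trim is applied by
  depth everywhere, not only on a named side: the depth mask is the
  reproducible rule; a directional description of where the trim bites
  is geography, not algorithm.
* **SDM stacks**: per-cell maximum over monthly occurrence-probability
  rasters, scored (default 0.4) strictly above the in-mask median —
  "above" is strict; the median cell itself scores 1.

## Cell membership

A cell belongs to a footprint iff its **center** lies inside the
polygon (deterministic, and directly checkable against a brute-force
point-in-polygon oracle, which the tests do with an independent
implementation). An any-overlap rule is available (`rule="overlap"`)
for users who prefer the more inclusive reading; it is strictly a
superset of the center rule.

All geometry is planar, in meters (project lon/lat upstream; inputs
that look geographic are rejected with instructions). Grids are
row-major, 0-based, origin at the upper-left corner.

## Combination and ranking

The four operators and their ordering (product ≤ lowest ≤ geometric ≤
arithmetic, equality iff all scores agree) are described in the README.
Two consequences worth stating precisely:

* only the product can produce combined scores below 0.1 (the minimum
  single-species score), and only where ≥ 2 scored species overlap;
* the product and geometric mean produce **identical dense rankings**
  on every input, because at fixed n one is a strictly monotone
  transform of the other.

Ranking is dense ("sports-style" 1, 2, 3, 3, 4, …): ties share the
minimum rank and the next distinct value takes the next integer.
Values within 1e-12 are treated as tied so that floating-point noise
does not split genuine ties.

## Suitability model

Submodel aggregates and the cross-submodel combination both use the
equally-weighted geometric mean. The cross-submodel rule is fixed by
the planning framework; the within-submodel rule is a package choice
made for consistency (the framework does not pin it down for
multi-member submodels) and is isolated in `assemble_submodel` should
a user want a different rule. Constraints are a hard mask: excluded
cells are removed before aggregation and never carry a suitability
value, rather than contributing zeros to a mean. Subregions are
modeled independently end to end; no cross-subregion normalization is
applied.

## Cluster detection (LISA)

Local Moran's I is computed as Iᵢ = zᵢ·Σⱼ wᵢⱼzⱼ with raw mean
deviations z and row-standardized contiguity weights (queen by
default), so that Σᵢ Iᵢ / Σᵢ zᵢ² equals global Moran's I when no cell
is isolated — this decomposition identity is asserted to 1e-9 in the
tests. Significance uses conditional permutation: each cell's value is
held fixed while neighbor values are drawn from the remaining cells;
the pseudo p-value is the min-tail (extreme + 1)/(permutations + 1).
Defaults — queen contiguity, 999 permutations, fixed seed — are
package choices (the source framework names the statistic but not its
parameters). Isolated cells are dropped with a warning; a constant
surface is an error (zero variance). Clusters are connected components
(same contiguity) of high-high cells with p < α (default 0.05).

## Precision siting (TOPSIS)

Square parcels use side s = round(√(area/cell_area)) cells — at 10-ac
cells, 500 ac → 7×7 = 490 ac; exact acreage and integer cell counts
cannot be reconciled, so the rounded square is the defined target.
Stage 1 ranks all parcels within a cluster by TOPSIS closeness over
distance-to-nearest-inlet (planar, from the footprint centroid),
mean relative fishing effort and mean relative vessel traffic, all as
costs with equal weights; stage 2 ranks the cluster winners across
clusters with the same criteria plus an optional generic
"oceanographic" cost column. The TOPSIS variant is the classical one:
vector (root-sum-square) normalization, Euclidean distances to the
ideal and anti-ideal, closeness C = D⁻/(D⁺+D⁻). Closeness is invariant
under positive rescaling of any criterion column; a weakly dominating
option never ranks below the option it dominates (both property-tested
on random matrices). A single candidate gets C = 1 by convention, with
a warning. Ties in closeness break deterministically: larger parcel
first, then grid position.

## Synthetic data

`hypothetical_fixture` is a deterministic three-species landscape (0.1
constricted; 0.4 and 0.8 broad and overlapping) containing every
overlap combination — the worked setting for the operator comparison.

`random_landscape` draws blob footprints by thresholding smoothed
uniform noise at the quantile matching the target occupancy.

`synthetic_gulf` is a miniature four-subregion shelf: a 40×120 lattice
of 40-acre (~402 m) cells, a deterministic depth gradient whose
50–150 m band forms the study area, eight species layers whose scores
mirror the case-study score multiset {0.1, 0.1, 0.2, 0.2, 0.3, 0.4,
0.4, 0.5} and which are built through the real derivations (buffered
hull + isobath trim at a 140 m synthetic shelf isobath, kernel-density
HUAs, a 95% volume contour, residence buffers, corridor unions, a
12-month SDM stack). One subregion is fully blocked by constraints;
a 16×16-cell low-conflict corridor (no species footprint, no
constraints, minimal fishing/vessel use, nearest inlet) is planted in
the West band as the designed suitability optimum. Cell and domain
sizes were chosen once to keep a full pipeline run around a second;
the cell area is a parameter, so the 10-ac configuration remains
exercised on small grids elsewhere in the suite.

What the synthetic shelf does **not** emulate: real bathymetry,
effort-biased and detection-biased observation processes, seasonal
dynamics, and realistic traffic/fisheries fields. Passing tests on it
demonstrate the pipeline's logical guarantees (constraint avoidance,
blocked-subregion behavior, determinism, corridor recovery), not
predictive skill on real data.

## Numerical notes and edge cases

* All in-mask scores live in (0,1]; zeros are reserved for constraints
  and rejected everywhere else.
* Raster round trips are bit-exact (repr-precision ASCII,
  round-trip-precision CSV parsing).
* The geometric-mean dilution of {0.1, 0.4} padded to n = 10 layers is
  0.04^(1/10) = 0.72478 — 0.72 at two decimals. A reference rendering
  of this series elsewhere prints 0.73; the package reports the
  computed value.
* Every stochastic step (synthetic generators, LISA permutations) is
  driven by an explicit seed; reruns are bit-identical.

## Limitations

* No on-the-fly reprojection; one planar CRS per analysis.
* Species-distribution models themselves (e.g. the monthly prediction
  stacks) are inputs, not fitted here.
* No gear- or activity-specific risk layers; the combined species
  layer expresses co-occurrence-weighted vulnerability, not
  interaction mechanism.
* The LISA permutation loop is pure numpy and comfortable to ~10⁴
  cells; very large grids would want a compiled neighbor kernel.
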