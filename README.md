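# seaplan

Marine spatial planning around protected species: a toolkit for siting
ocean industries (offshore aquaculture, wind energy, and similar fixed
installations) in the places that least conflict with vulnerable marine
species.

The package is aimed at spatial ecologists and marine planners who need a
transparent, reproducible alternative to ad-hoc GIS workflows: every step —
from statutory vulnerability scoring to the final ranked siting options —
is an importable, tested Python function operating on plain-text rasters
and GeoJSON.

## The model

1. **Vulnerability scoring.** Each protected species or stock gets a
   suitability score from a rubric over its statutory listing (ESA or
   MMPA), status, population trend, and population-size class (small ≤ 500
   individuals): from 0.1 (ESA Endangered, declining and/or small
   population) to 0.8 (MMPA-listed, large population). Inside the species'
   spatial footprint every grid cell takes that score; outside it the
   species contributes a 1 (no conflict). Footprints are derived from
   whatever data exist: kernel-density high-use areas (upper two
   quartiles), 95% volume contours, fixed-radius residence buffers,
   buffered convex hulls trimmed to an isobath, or thresholded
   species-distribution-model stacks (per-cell maximum over monthly
   predictions, cut at the median).

2. **Layer combination.** Overlapping species layers x₁…xₙ ∈ (0,1] are
   combined cellwise by one of four operators: product ρ = Πxᵢ, geometric
   mean g = (Πxᵢ)^{1/n}, arithmetic mean μ = Σxᵢ/n, or lowest score
   l = min xᵢ. By the AM–GM inequality ρ ≤ l ≤ g ≤ μ everywhere. The
   product is the recommended operator: it is the only one that can fall
   below the most vulnerable single score when species co-occur, so
   overlap always deepens concern, while both means dilute a rare,
   range-restricted species toward 1 as absent layers are added.

3. **Cumulative suitability.** Thematic submodels (national security;
   industry/navigation; fishing; natural & cultural resources — the
   combined species layer enters here) are each aggregated by
   equally-weighted geometric mean; binary constraint cells are eliminated
   outright; the surviving cells get the geometric mean across submodels.

4. **Precision siting.** Local Moran's I (LISA, queen contiguity, 999
   conditional permutations) finds statistically significant
   high-suitability clusters (p < 0.05). Axis-aligned square parcels of
   2000/1500/1000/500 acres are enumerated inside each cluster, ranked
   within clusters by TOPSIS (distance to inlets, relative fishing effort,
   relative vessel traffic — all costs), and cluster winners re-ranked
   across clusters; up to three options are returned per subregion,
   followed by a yes/no conflict matrix against each species layer.

## Worked example

`examples/02_combining_layers.py` builds the three-species teaching
landscape (scores 0.1, 0.4, 0.8) and prints:

```
geometric mean of {0.1, 0.4} + 1 absent layers (n=3): 0.34
geometric mean of {0.1, 0.4} + 2 absent layers (n=4): 0.45
geometric mean of {0.1, 0.4} + 3 absent layers (n=5): 0.53
geometric mean of {0.1, 0.4} + 8 absent layers (n=10): 0.72

combined score at a cell where all three species overlap:
  product    0.032
  geometric  0.317
  arithmetic 0.433
  lowest     0.100

product vs geometric rank disagreement: 0%
```

The dilution series is the case against averaging: a cell hosting an
endangered species (0.1) and a threatened one (0.4) looks steadily more
"suitable" under the geometric mean as more non-overlapping species are
added to the model, while the product (0.04) is unaffected. The 0%
disagreement line shows the product and geometric mean always rank cells
identically (one is a monotone transform of the other at fixed n) — the
choice between them is about contrast, not order.

`examples/04_end_to_end_siting.py` runs the full pipeline on a miniature
four-subregion synthetic shelf and prints the final options, e.g.:

```
suitability surface: 2395 usable cells, median 0.690
significant high-suitability clusters: 5

final siting options (max 3 per subregion):
  W-1: West, 500 ac, inlet 1.8 km, closeness 1.000
  E-1: East, 500 ac, inlet 7.3 km, closeness 0.000

blocked subregion (Southeast) options: 0
planted low-conflict corridor hosts an option: True
species conflicts: 2 of 16 layer-option pairs
```

The fully constraint-blocked subregion yields no options, and the planted
low-conflict corridor — the construction's suitability optimum — is where
the top West option lands.

## Command line

A thin CLI wraps the library for shell use:

```sh
seaplan synth --seed 1 --out scenario/     # write a synthetic scenario
seaplan run scenario/config.yaml           # full pipeline
seaplan score ESA Endangered declining small
seaplan combine --grid g.json --method product -o out.asc a.asc b.asc
```

Subcommands `compare`, `suitability`, `cluster`, `site`, `conflicts` and
`layers` expose the individual stages.

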