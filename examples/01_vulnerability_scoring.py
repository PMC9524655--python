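"""Score species by statutory vulnerability and build a scored layer.

The rubric converts (statute, status, trend, population class) into a
suitability score: 0.1 = most vulnerable (ESA Endangered, declining
and/or tiny population), 0.8 = least vulnerable (MMPA-listed stock with
a large population).  Inside a species' footprint every planning cell
takes that score; outside it the species contributes a 1 (no conflict).
"""

import numpy as np
from shapely.geometry import box

from seaplan import PlanningGrid, VulnerabilityRecord, build_species_layer, \
    score_from_rubric

for args in [
    ("ESA", "Endangered", "declining", "small"),
    ("ESA", "Endangered", "increasing", "unspecified"),
    ("ESA", "Threatened", "unknown", "unspecified"),
    ("MMPA", "Listed", "stable", "large"),
]:
    print(f"{'/'.join(args):55s} -> {score_from_rubric(*args)}")

# a 30x30 grid of 10-acre cells; the footprint is a core + extended union
grid = PlanningGrid(n_rows=30, n_cols=30, origin=(0.0, 30 * 201.168))
s = grid.cell_size
record = VulnerabilityRecord("example_whale", "ESA", "Endangered",
                             "declining", "small")
layer = build_species_layer(
    grid, [box(2 * s, 2 * s, 10 * s, 10 * s),
           box(8 * s, 8 * s, 20 * s, 14 * s)], record
)
fp = layer.values < 1
print(f"\nfootprint: {fp.sum()} of {grid.study_mask.sum()} cells scored "
      f"{record.score}; all other cells score 1")
print("distinct layer values:", sorted(float(v) for v in np.unique(layer.values)))
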