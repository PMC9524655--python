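"""Combining overlapping scored layers into one conflict surface.

Four cellwise operators are supported for scores ``x1..xn`` in (0, 1]:

* ``product``     — x1·x2·…·xn (recommended: the only operator that can
  drop below the most vulnerable single score when species overlap, so
  overlap always deepens concern);
* ``geometric``   — (x1·…·xn)^(1/n);
* ``arithmetic``  — (x1+…+xn)/n;
* ``lowest``      — min(x1,…,xn).

By the AM–GM inequality ``product ≤ lowest ≤ geometric ≤ arithmetic``
everywhere, with equality only where all scores agree.  Because the
geometric mean is a monotone transform of the product at fixed n, the
two produce identical cell rankings; both averaging operators, however,
drift toward 1 as more non-overlapping (all-1) layers are added — so a
rare, range-restricted species gets diluted.  ``rank_cells`` implements
dense ranking (ties share the minimum rank: 1, 2, 3, 3, 4, …), rank 1 =
lowest score = greatest conservation concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import PlanningGrid, ScoredLayer

METHODS = ("product", "geometric", "arithmetic", "lowest")

#: scores closer than this are tied for ranking purposes
RANK_TIE_TOL = 1e-12


@dataclass
class CombinedLayer:
    """Cellwise combination of several scored layers."""

    grid: PlanningGrid
    values: np.ndarray
    method: str
    n_layers: int
    source_names: list[str] = field(default_factory=list)

    @property
    def in_mask(self) -> np.ndarray:
        return self.values[self.grid.study_mask]


def _validate_scores(scores: np.ndarray) -> None:
    if scores.size == 0:
        raise ValueError("need at least one score")
    if np.any(scores <= 0) or np.any(scores > 1):
        raise ValueError(
            "scores must lie in (0, 1]; hard exclusions (zeros) belong to "
            "the constraints submodel, not to layer combination"
        )


def combine_cell(scores, method: str) -> float:
    """Combine the scores present in one cell with one operator.

    >>> round(combine_cell([0.1, 0.4, 1.0], "geometric"), 2)
    0.34
    """
    scores = np.asarray(scores, dtype=float)
    _validate_scores(scores)
    if method == "product":
        return float(np.prod(scores))
    if method == "geometric":
        return float(np.exp(np.mean(np.log(scores))))
    if method == "arithmetic":
        return float(np.mean(scores))
    if method == "lowest":
        return float(np.min(scores))
    raise ValueError(f"unknown combination method {method!r}; "
                     f"expected one of {METHODS}")


def combine_layers(layers: list[ScoredLayer], method: str) -> CombinedLayer:
    """Cellwise combination of a stack of layers on a shared grid."""
    if not layers:
        raise ValueError("need at least one layer")
    grid = layers[0].grid
    for lyr in layers[1:]:
        if not grid.same_lattice(lyr.grid):
            raise ValueError(
                f"layer {lyr.name!r} is not on the same lattice as "
                f"{layers[0].name!r}"
            )
    stack = np.stack([lyr.values for lyr in layers])
    inside = grid.study_mask
    flat = stack[:, inside]
    _validate_scores(flat[np.isfinite(flat)])
    if np.any(~np.isfinite(flat)):
        raise ValueError("layers disagree about which cells are in-mask")
    if method == "product":
        combined = np.prod(flat, axis=0)
    elif method == "geometric":
        combined = np.exp(np.mean(np.log(flat), axis=0))
    elif method == "arithmetic":
        combined = np.mean(flat, axis=0)
    elif method == "lowest":
        combined = np.min(flat, axis=0)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    vals = np.full(grid.shape, np.nan)
    vals[inside] = combined
    return CombinedLayer(
        grid=grid, values=vals, method=method, n_layers=len(layers),
        source_names=[lyr.name for lyr in layers],
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def dense_rank(values: np.ndarray, tol: float = RANK_TIE_TOL) -> np.ndarray:
    """Dense ranks of a 1-D vector, ascending: the lowest value gets
    rank 1, ties share a rank, and the next distinct value takes the
    next integer (1, 2, 3, 3, 4, …).  Values within ``tol`` are tied."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    rank = 0
    prev = None
    for idx in order:
        v = values[idx]
        if prev is None or v - prev > tol:
            rank += 1
            prev = v
        ranks[idx] = rank
    return ranks


def rank_cells(combined: CombinedLayer, direction: str = "ascending"
               ) -> np.ndarray:
    """Per-cell dense rank map; rank 1 = greatest concern (lowest
    combined score) under the default ascending direction.  Cells
    outside the mask get 0."""
    inside = combined.grid.study_mask
    vals = combined.values[inside]
    if direction == "descending":
        vals = -vals
    elif direction != "ascending":
        raise ValueError("direction must be 'ascending' or 'descending'")
    ranks = np.zeros(combined.grid.shape, dtype=int)
    ranks[inside] = dense_rank(vals)
    return ranks


# ---------------------------------------------------------------------------
# method comparison diagnostics
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    """Spread statistics and pairwise rank disagreement for the four
    combination operators."""

    spread: pd.DataFrame            # per-method median/min/max/quartiles
    disagreement: pd.DataFrame      # long form: method_a, method_b, subregion, fraction
    rank_maps: dict[str, np.ndarray]
    combined: dict[str, CombinedLayer]

    def disagreement_matrix(self, subregion: str = "all") -> pd.DataFrame:
        sub = self.disagreement[self.disagreement["subregion"] == subregion]
        return sub.pivot(index="method_a", columns="method_b",
                         values="fraction")


def compare_methods(layers: list[ScoredLayer],
                    subregions: bool = True) -> MethodComparison:
    """Combine a layer stack with every operator and report per-method
    spread plus the fraction of cells whose dense ranks disagree for
    each method pair (overall and per subregion)."""
    combined = {m: combine_layers(layers, m) for m in METHODS}
    grid = combined["product"].grid
    inside = grid.study_mask

    spread_rows = []
    for m in METHODS:
        v = combined[m].in_mask
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        spread_rows.append({
            "method": m, "median": med, "min": v.min(), "max": v.max(),
            "q1": q1, "q3": q3,
        })
    spread = pd.DataFrame(spread_rows).set_index("method")

    rank_maps = {m: rank_cells(combined[m]) for m in METHODS}

    regions: dict[str, np.ndarray] = {"all": inside}
    if subregions and grid.subregion_id is not None:
        for name in grid.subregion_names:
            regions[name] = grid.subregion_mask(name)

    rows = []
    for i, ma in enumerate(METHODS):
        for mb in METHODS[i + 1:]:
            for region_name, region_mask in regions.items():
                if not region_mask.any():
                    frac = 0.0
                else:
                    # ranks recomputed within the region so the comparison
                    # is self-contained, mirroring independent subregion models
                    ra = dense_rank(combined[ma].values[region_mask])
                    rb = dense_rank(combined[mb].values[region_mask])
                    frac = float(np.mean(ra != rb))
                rows.append({"method_a": ma, "method_b": mb,
                             "subregion": region_name, "fraction": frac})
    disagreement = pd.DataFrame(rows)
    return MethodComparison(spread=spread, disagreement=disagreement,
                            rank_maps=rank_maps, combined=combined)
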