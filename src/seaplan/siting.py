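"""Cluster detection and precision siting on a suitability surface.

Stage 1 finds statistically significant high-suitability clusters with
the local Moran's I statistic (LISA) under conditional permutation
(queen contiguity, 999 permutations by default).  Stage 2 is a
two-stage precision-siting model: axis-aligned square parcels of 2000,
1500, 1000 and 500 acres are enumerated inside each high-high cluster,
ranked within clusters by TOPSIS (proximity to inlets, lowest relative
fishing effort, lowest relative vessel traffic), and the cluster
winners are re-ranked across clusters with an extended criteria set.
The final deliverable is up to three siting options per subregion and a
yes/no conflict matrix against the individual species layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import footprint_mask
from .grid import PlanningGrid, ScoredLayer
from .suitability import SuitabilitySurface

_QUEEN_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                  (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1)]

QUADRANTS = {0: "", 1: "HH", 2: "LH", 3: "LL", 4: "HL"}

DEFAULT_SIZES_AC = (2000.0, 1500.0, 1000.0, 500.0)


# ---------------------------------------------------------------------------
# local Moran's I
# ---------------------------------------------------------------------------

@dataclass
class LisaResult:
    """Per-cell local Moran's I with conditional-permutation p-values.

    ``local_i[i] = z_i * sum_j w_ij z_j`` with row-standardized weights
    and raw mean deviations ``z``, so that ``sum(local_i) / sum(z**2)``
    equals global Moran's I when no cell is isolated.
    """

    grid: PlanningGrid
    local_i: np.ndarray
    p_value: np.ndarray
    quadrant: np.ndarray          # int codes, see QUADRANTS
    scheme: str
    permutations: int
    seed: int
    analysis_mask: np.ndarray     # cells that entered the analysis

    def global_moran(self) -> float:
        m = self.analysis_mask
        vals = self._values[m]
        z = vals - vals.mean()
        return float(np.sum(self.local_i[m]) / np.sum(z**2))

    _values: np.ndarray = field(default=None, repr=False)  # type: ignore


def _neighbor_offsets(scheme: str) -> list[tuple[int, int]]:
    if scheme == "queen":
        return _QUEEN_OFFSETS
    if scheme == "rook":
        return _ROOK_OFFSETS
    raise ValueError(f"unknown contiguity scheme {scheme!r}")


def _neighbor_lists(valid: np.ndarray, scheme: str) -> list[np.ndarray]:
    """Per valid cell, the flat indices (into the valid-cell vector) of
    its valid contiguity neighbors."""
    n_rows, n_cols = valid.shape
    idx_of = -np.ones(valid.shape, dtype=int)
    rows, cols = np.nonzero(valid)
    idx_of[rows, cols] = np.arange(rows.size)
    offsets = _neighbor_offsets(scheme)
    out = []
    for r, c in zip(rows, cols):
        nbrs = []
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and valid[rr, cc]:
                nbrs.append(idx_of[rr, cc])
        out.append(np.asarray(nbrs, dtype=int))
    return out


def local_morans(surface: "SuitabilitySurface | np.ndarray",
                 grid: PlanningGrid | None = None,
                 scheme: str = "queen",
                 permutations: int = 999,
                 seed: int = 0) -> LisaResult:
    """Local Moran's I on the usable cells of a suitability surface.

    Significance comes from conditional permutation: each cell's value
    is held fixed while its neighbors' values are drawn (without
    replacement, per draw) from the remaining cells; the pseudo p-value
    is the min-tail ``(extreme + 1) / (permutations + 1)``.  Cells with
    no valid neighbor are dropped with a warning.
    """
    if isinstance(surface, SuitabilitySurface):
        grid = surface.grid
        values = surface.values
        valid = surface.usable_mask & np.isfinite(values)
    else:
        values = np.asarray(surface, dtype=float)
        if grid is None:
            raise ValueError("pass a grid when the surface is a bare array")
        valid = grid.study_mask & np.isfinite(values)
    if valid.sum() < 9:
        raise ValueError("need at least 9 cells for cluster detection")

    nbr = _neighbor_lists(valid, scheme)
    isolated = np.array([len(v) == 0 for v in nbr])
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated cells have no neighbors and "
            "are excluded from the cluster analysis",
            stacklevel=2,
        )
        keep = valid.copy()
        keep[tuple(np.nonzero(valid)[k][isolated] for k in (0, 1))] = False
        valid = keep
        nbr = _neighbor_lists(valid, scheme)

    x = values[valid]
    n = x.size
    if np.allclose(x, x[0]):
        raise ValueError("surface is constant; local Moran's I is undefined")
    z = x - x.mean()

    lag = np.array([z[nb].mean() for nb in nbr])
    local = z * lag

    rng = np.random.default_rng(seed)
    p_flat = np.ones(n)
    for i in range(n):
        c = len(nbr[i])
        # sample neighbor values from z without z_i (conditional scheme)
        draws = rng.integers(0, n - 1, size=(permutations, c))
        draws = draws + (draws >= i)
        sim_lag = z[draws].mean(axis=1)
        sim_i = z[i] * sim_lag
        larger = int(np.sum(sim_i >= local[i]))
        p_flat[i] = (min(larger, permutations - larger) + 1) / (permutations + 1)

    quad_flat = np.where(z > 0, np.where(lag > 0, 1, 4),
                         np.where(lag > 0, 2, 3))

    local_i = np.full(values.shape, np.nan)
    p_value = np.full(values.shape, np.nan)
    quadrant = np.zeros(values.shape, dtype=int)
    local_i[valid] = local
    p_value[valid] = p_flat
    quadrant[valid] = quad_flat
    return LisaResult(
        grid=grid, local_i=local_i, p_value=p_value, quadrant=quadrant,
        scheme=scheme, permutations=permutations, seed=seed,
        analysis_mask=valid, _values=values,
    )


def significant_clusters(lisa: LisaResult, alpha: float = 0.05) -> np.ndarray:
    """Labeled connected components (same contiguity as the LISA run)
    of high-high cells with p below ``alpha``; 0 = no cluster."""
    hh = (lisa.quadrant == 1) & (lisa.p_value < alpha)
    structure = np.ones((3, 3), dtype=int) if lisa.scheme == "queen" \
        else ndimage.generate_binary_structure(2, 1)
    labels, _ = ndimage.label(hh, structure=structure)
    return labels


# ---------------------------------------------------------------------------
# square parcel fitting
# ---------------------------------------------------------------------------

@dataclass
class SitingOption:
    """One candidate square parcel inside a significant cluster."""

    subregion: str
    cluster_id: int
    row0: int
    col0: int
    side: int                      # cells per edge
    size_class_ac: float
    criteria: dict = field(default_factory=dict)
    topsis_closeness: float = np.nan
    within_cluster_rank: int = 0
    final_rank: int = 0
    option_id: str = ""

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0:self.row0 + self.side,
          self.col0:self.col0 + self.side] = True
        return m

    def centroid(self, grid: PlanningGrid) -> tuple[float, float]:
        s = grid.cell_size
        x0, y0 = grid.origin
        return (
            x0 + (self.col0 + self.side / 2) * s,
            y0 - (self.row0 + self.side / 2) * s,
        )


def square_side(size_ac: float, cell_ac: float) -> int:
    """Cells per edge of the square approximating ``size_ac``:
    ``round(sqrt(size/cell))`` (2000 ac at 10-ac cells -> 14)."""
    return int(round(np.sqrt(size_ac / cell_ac)))


def fit_square_options(cluster_map: np.ndarray, cluster_id: int,
                       grid: PlanningGrid,
                       sizes_ac=DEFAULT_SIZES_AC) -> list[SitingOption]:
    """Enumerate every axis-aligned square block of each size class
    that fits entirely inside one labeled cluster."""
    inside = cluster_map == cluster_id
    if not inside.any():
        return []
    # integral image for O(1) block-sum queries
    ii = np.zeros((inside.shape[0] + 1, inside.shape[1] + 1), dtype=int)
    ii[1:, 1:] = np.cumsum(np.cumsum(inside, axis=0), axis=1)
    options = []
    rows, cols = np.nonzero(inside)
    if grid.subregion_id is not None and grid.subregion_names:
        code = int(np.bincount(grid.subregion_id[inside]).argmax())
        subregion = grid.subregion_names[code]
    else:
        subregion = ""
    for size_ac in sorted(sizes_ac, reverse=True):
        s = square_side(size_ac, grid.cell_area_ac)
        if s < 1:
            continue
        for r in range(inside.shape[0] - s + 1):
            for c in range(inside.shape[1] - s + 1):
                block = ii[r + s, c + s] - ii[r, c + s] - ii[r + s, c] + ii[r, c]
                if block == s * s:
                    options.append(SitingOption(
                        subregion=subregion, cluster_id=cluster_id,
                        row0=r, col0=c, side=s, size_class_ac=size_ac,
                    ))
    return options


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------

def topsis_closeness(matrix: np.ndarray, benefit_flags,
                     weights=None) -> np.ndarray:
    """Relative closeness to the ideal solution for each alternative.

    Columns are vector-normalized (root sum of squares), weighted, and
    compared by Euclidean distance to the ideal (best per column) and
    anti-ideal (worst per column) vectors; closeness is
    ``D- / (D+ + D-)`` in [0, 1], higher = better.  A single
    alternative has both distances 0 and gets closeness 1 by
    convention.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("criteria matrix must be 2-D with >=1 alternative")
    if not np.all(np.isfinite(m)):
        raise ValueError("criteria matrix must be finite")
    flags = np.asarray(benefit_flags, dtype=bool)
    if flags.size != m.shape[1]:
        raise ValueError("one benefit/cost flag per criterion required")
    if m.shape[0] == 1:
        warnings.warn("single alternative: closeness defined as 1",
                      stacklevel=2)
        return np.ones(1)
    w = np.full(m.shape[1], 1.0 / m.shape[1]) if weights is None \
        else np.asarray(weights, dtype=float) / np.sum(weights)
    norms = np.sqrt(np.sum(m**2, axis=0))
    norms[norms == 0] = 1.0  # all-zero column carries no information
    v = m / norms * w
    ideal = np.where(flags, v.max(axis=0), v.min(axis=0))
    anti = np.where(flags, v.min(axis=0), v.max(axis=0))
    d_pos = np.sqrt(np.sum((v - ideal) ** 2, axis=1))
    d_neg = np.sqrt(np.sum((v - anti) ** 2, axis=1))
    denom = d_pos + d_neg
    closeness = np.where(denom == 0, 1.0, d_neg / np.where(denom == 0, 1, denom))
    return closeness


def topsis_rank(options: list[SitingOption], criteria_names: list[str],
                benefit_flags, weights=None) -> list[SitingOption]:
    """Rank options by descending TOPSIS closeness over the named
    criteria (read from each option's ``criteria`` record); ties break
    deterministically by larger parcel, then position."""
    if not options:
        return []
    matrix = np.array([[o.criteria[c] for c in criteria_names]
                       for o in options])
    closeness = topsis_closeness(matrix, benefit_flags, weights)
    for o, c in zip(options, closeness):
        o.topsis_closeness = float(c)
    return sorted(
        options,
        key=lambda o: (-o.topsis_closeness, -o.size_class_ac, o.row0, o.col0),
    )


# ---------------------------------------------------------------------------
# criteria + selection
# ---------------------------------------------------------------------------

def attach_criteria(options: list[SitingOption], grid: PlanningGrid,
                    inlets_xy: np.ndarray,
                    fishing_effort: np.ndarray,
                    vessel_traffic: np.ndarray,
                    oceanographic: np.ndarray | None = None) -> None:
    """Fill each option's criteria record: planar distance (km) from
    the footprint centroid to the nearest inlet, and mean relative
    fishing effort / vessel traffic (/ optional oceanographic cost)
    over the footprint."""
    inlets = np.atleast_2d(np.asarray(inlets_xy, dtype=float))
    for o in options:
        fp = o.footprint(grid.shape)
        cx, cy = o.centroid(grid)
        d = np.hypot(inlets[:, 0] - cx, inlets[:, 1] - cy).min() / 1000.0
        o.criteria["distance_to_inlet"] = float(d)
        o.criteria["fishing_effort"] = float(np.nanmean(fishing_effort[fp]))
        o.criteria["vessel_traffic"] = float(np.nanmean(vessel_traffic[fp]))
        if oceanographic is not None:
            o.criteria["oceanographic"] = float(np.nanmean(oceanographic[fp]))


STAGE1_CRITERIA = ["distance_to_inlet", "fishing_effort", "vessel_traffic"]


def rank_two_stage(options_by_cluster: dict[int, list[SitingOption]],
                   use_oceanographic: bool = False
                   ) -> list[SitingOption]:
    """Stage 1: TOPSIS within each cluster (distance to inlet, fishing
    effort, vessel traffic — all costs).  Stage 2: the cluster winners
    compete across clusters on the extended criteria set."""
    winners = []
    for cid, opts in sorted(options_by_cluster.items()):
        if not opts:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = topsis_rank(opts, STAGE1_CRITERIA,
                                 benefit_flags=[False, False, False])
        for k, o in enumerate(ranked, start=1):
            o.within_cluster_rank = k
        winners.append(ranked[0])
    if not winners:
        return []
    stage2 = STAGE1_CRITERIA + (["oceanographic"] if use_oceanographic else [])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = topsis_rank(winners, stage2,
                            benefit_flags=[False] * len(stage2))
    for k, o in enumerate(final, start=1):
        o.final_rank = k
    return final


def select_final_options(ranked: list[SitingOption],
                         per_subregion: int = 3) -> list[SitingOption]:
    """Top ``per_subregion`` stage-2 options in each subregion; fewer
    (possibly zero) where the clusters cannot supply them."""
    out: list[SitingOption] = []
    by_sub: dict[str, list[SitingOption]] = {}
    for o in ranked:
        by_sub.setdefault(o.subregion, []).append(o)
    for sub, opts in by_sub.items():
        opts = sorted(opts, key=lambda o: o.final_rank)
        if 0 < len(opts) < per_subregion:
            warnings.warn(
                f"subregion {sub!r}: only {len(opts)} option(s) available "
                f"of {per_subregion} requested",
                stacklevel=2,
            )
        chosen = opts[:per_subregion]
        for k, o in enumerate(chosen, start=1):
            o.option_id = f"{sub[:1] or 'X'}-{k}" if sub else f"opt-{k}"
        out.extend(chosen)
    return out


# ---------------------------------------------------------------------------
# conflict matrix
# ---------------------------------------------------------------------------

@dataclass
class ConflictReport:
    """Yes/No interaction table (rows = species layers, columns =
    siting options) with summary counts."""

    table: pd.DataFrame

    @property
    def total_pairs(self) -> int:
        return int(self.table.size)

    @property
    def n_conflicts(self) -> int:
        return int((self.table == "Yes").to_numpy().sum())

    def n_conflicts_excluding(self, layer_names) -> int:
        keep = self.table.drop(index=list(layer_names), errors="ignore")
        return int((keep == "Yes").to_numpy().sum())

    def percentages(self) -> dict[str, float]:
        return {"conflict_pct": 100.0 * self.n_conflicts / self.total_pairs}


def conflict_matrix(final_options: list[SitingOption],
                    species_layers: list[ScoredLayer]) -> ConflictReport:
    """Yes iff any footprint cell carries the layer's scored (non-1)
    value — i.e. the parcel overlaps that species' footprint."""
    cols = {}
    for o in final_options:
        oid = o.option_id or f"{o.subregion[:1]}-{o.final_rank}"
        fp = o.footprint(species_layers[0].grid.shape) if species_layers \
            else None
        col = []
        for lyr in species_layers:
            col.append("Yes" if bool(footprint_mask(lyr)[fp].any()) else "No")
        cols[oid] = col
    table = pd.DataFrame(cols, index=[lyr.name for lyr in species_layers])
    return ConflictReport(table=table)


def count_conflicts(table: pd.DataFrame, exclude=()) -> dict[str, float]:
    """Summary counts for a Yes/No interaction table (as produced by
    ``conflict_matrix`` or loaded from CSV): total layer-option pairs,
    conflicts, conflicts excluding the named layers, and exact
    percentages."""
    report = ConflictReport(table=table)
    n_excl = report.n_conflicts_excluding(exclude)
    return {
        "total_pairs": report.total_pairs,
        "n_conflicts": report.n_conflicts,
        "n_conflicts_excluding": n_excl,
        "conflict_pct": 100.0 * report.n_conflicts / report.total_pairs,
        "conflict_pct_excluding": 100.0 * n_excl / report.total_pairs,
    }
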