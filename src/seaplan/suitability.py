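"""Submodel assembly and the cumulative suitability model.

Siting considerations are grouped into thematic submodels (national
security; industry, navigation and transportation; fishing and
aquaculture; natural and cultural resources) plus a binary constraints
submodel.  Constraint cells (score 0) are eliminated outright; on the
remaining cells the submodel aggregates are combined with an
equally-weighted geometric mean, giving a cumulative suitability score
in (0, 1] per cell.  The combined protected-species layer enters as one
member of the natural-and-cultural-resources submodel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .combine import CombinedLayer, combine_layers
from .grid import PlanningGrid, ScoredLayer

SUBMODEL_NAMES = (
    "national_security",
    "industry_nav_transport",
    "fishing_aquaculture",
    "natural_cultural",
    "constraints",
)


@dataclass
class Submodel:
    """One thematic group of scored layers with its per-cell aggregate
    (equally-weighted geometric mean of the members)."""

    name: str
    member_layers: list[ScoredLayer]
    aggregate: np.ndarray

    @property
    def grid(self) -> PlanningGrid:
        return self.member_layers[0].grid


@dataclass
class SuitabilitySurface:
    """Constraint-masked cumulative suitability in (0, 1]; excluded
    cells carry NaN and are flagged in ``excluded_mask``."""

    grid: PlanningGrid
    values: np.ndarray
    excluded_mask: np.ndarray
    submodel_names: list[str] = field(default_factory=list)

    @property
    def usable_mask(self) -> np.ndarray:
        """In-study cells that survived the constraints."""
        return self.grid.study_mask & ~self.excluded_mask


def assemble_submodel(name: str, layers: list[ScoredLayer]) -> Submodel:
    """Aggregate member layers into one submodel by equally-weighted
    geometric mean.  Zeros are not allowed here — hard exclusions
    belong to the constraints submodel."""
    if name not in SUBMODEL_NAMES:
        raise ValueError(f"unknown submodel {name!r}; expected one of "
                         f"{SUBMODEL_NAMES}")
    if name == "constraints":
        raise ValueError(
            "the constraints submodel is binary; build it with "
            "constraints_submodel()"
        )
    combined: CombinedLayer = combine_layers(layers, "geometric")
    return Submodel(name=name, member_layers=list(layers),
                    aggregate=combined.values)


def constraints_submodel(grid: PlanningGrid,
                         excluded: np.ndarray) -> Submodel:
    """Binary constraints submodel: 0 = excluded, 1 = available."""
    excluded = np.asarray(excluded, dtype=bool)
    if excluded.shape != grid.shape:
        raise ValueError("constraints mask shape does not match grid")
    vals = np.where(excluded, 0.0, 1.0)
    vals[~grid.study_mask] = np.nan
    layer = ScoredLayer.__new__(ScoredLayer)  # bypass (0,1] validation
    layer.grid = grid
    layer.values = vals
    layer.name = "constraints"
    layer.provenance = "binary exclusion mask"
    return Submodel(name="constraints", member_layers=[layer],
                    aggregate=vals)


def cumulative_model(submodels: list[Submodel],
                     constraints: Submodel | None = None
                     ) -> SuitabilitySurface:
    """Equally-weighted geometric mean across submodel aggregates,
    after eliminating constraint cells.

    Constraints are a hard mask applied before aggregation — excluded
    cells never receive a suitability value.
    """
    non_constraint = [s for s in submodels if s.name != "constraints"]
    if constraints is None:
        found = [s for s in submodels if s.name == "constraints"]
        constraints = found[0] if found else None
    if not non_constraint:
        raise ValueError("need at least one non-constraint submodel")
    grid = non_constraint[0].grid
    excluded = np.zeros(grid.shape, dtype=bool)
    if constraints is not None:
        excluded = (constraints.aggregate == 0.0) & grid.study_mask
    usable = grid.study_mask & ~excluded
    if not usable.any():
        warnings.warn("all cells are excluded by constraints; empty "
                      "suitability surface", stacklevel=2)
        return SuitabilitySurface(
            grid=grid, values=np.full(grid.shape, np.nan),
            excluded_mask=excluded,
            submodel_names=[s.name for s in non_constraint],
        )
    stack = np.stack([s.aggregate for s in non_constraint])
    flat = stack[:, usable]
    if np.any(~np.isfinite(flat)) or np.any(flat <= 0) or np.any(flat > 1):
        raise ValueError(
            "submodel aggregates must lie in (0, 1] on all usable cells"
        )
    vals = np.full(grid.shape, np.nan)
    vals[usable] = np.exp(np.mean(np.log(flat), axis=0))
    return SuitabilitySurface(
        grid=grid, values=vals, excluded_mask=excluded,
        submodel_names=[s.name for s in non_constraint],
    )
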