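"""Planning-grid data model shared by every stage of the siting pipeline.

The planning domain is a regular lattice of square cells in a planar
projected coordinate system (meters).  Each cell either belongs to the
study area (and then to exactly one named subregion) or lies outside it.
Per-cell quantities (vulnerability scores, suitability, depth, densities)
are stored as 2-D float arrays aligned to the grid, with ``NaN`` marking
cells outside the study mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: square meters per acre (international acre)
ACRE_M2 = 4046.8564224

#: closed vocabulary for point-observation sources
POINT_SOURCES = frozenset({"encounter", "acoustic", "satellite", "aerial", "observer"})


@dataclass(frozen=True)
class PlanningGrid:
    """A regular planar grid of square cells, row-major, origin at the
    upper-left corner.

    Parameters
    ----------
    n_rows, n_cols
        Lattice shape.
    cell_area_ac
        Cell area in acres (default 10 ac = 4.0469 ha); the cell edge
        length in meters is derived from it.
    origin
        Planar ``(x, y)`` of the grid's upper-left corner, meters.
    subregion_id
        Integer label per cell (``-1`` = no subregion / outside study
        area); names for the labels live in ``subregion_names``.
    study_mask
        Boolean per cell; ``True`` = inside the study area.
    """

    n_rows: int
    n_cols: int
    cell_area_ac: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    subregion_id: np.ndarray | None = None
    subregion_names: tuple[str, ...] = ()
    study_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.study_mask is None:
            object.__setattr__(
                self, "study_mask", np.ones(self.shape, dtype=bool)
            )
        mask = np.asarray(self.study_mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("study_mask shape does not match grid shape")
        object.__setattr__(self, "study_mask", mask)
        if self.subregion_id is not None:
            sub = np.asarray(self.subregion_id, dtype=int)
            if sub.shape != self.shape:
                raise ValueError("subregion_id shape does not match grid shape")
            if np.any((sub < 0) & mask):
                raise ValueError("every in-mask cell needs a subregion label")
            object.__setattr__(self, "subregion_id", sub)

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_area_ac * ACRE_M2

    @property
    def cell_size(self) -> float:
        """Cell edge length in meters (``sqrt`` of the cell area)."""
        return float(np.sqrt(self.cell_area_m2))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Planar ``(x, y)`` coordinates of every cell center, shape
        ``(n_rows, n_cols)`` each.  Row 0 is the northernmost row."""
        s = self.cell_size
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * s
        y = y0 - (rows + 0.5) * s
        return np.meshgrid(x, y)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """``(minx, miny, maxx, maxy)`` of one cell."""
        s = self.cell_size
        x0, y0 = self.origin
        return (x0 + col * s, y0 - (row + 1) * s, x0 + (col + 1) * s, y0 - row * s)

    # -- bookkeeping --------------------------------------------------

    def subregion_mask(self, name: str) -> np.ndarray:
        if self.subregion_id is None:
            raise ValueError("grid has no subregions")
        try:
            code = self.subregion_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown subregion {name!r}") from exc
        return (self.subregion_id == code) & self.study_mask

    def same_lattice(self, other: "PlanningGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_area_ac, other.cell_area_ac)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ScoredLayer:
    """Per-cell suitability score in ``(0, 1]`` for one species or one
    planning consideration.

    A score of 1 means no siting conflict; lower scores mean greater
    conflict or vulnerability.  Cells outside a species' footprint hold
    exactly 1; cells outside the study mask hold ``NaN``.
    """

    grid: PlanningGrid
    values: np.ndarray
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {vals.shape} does not "
                f"match grid shape {self.grid.shape}"
            )
        self.values = vals
        self.validate()

    def validate(self) -> None:
        inside = self.values[self.grid.study_mask]
        bad = ~np.isnan(inside) & ((inside <= 0) | (inside > 1))
        if np.any(bad):
            raise ValueError(
                f"layer {self.name!r}: {int(bad.sum())} in-mask values fall "
                "outside (0, 1]"
            )

    @property
    def in_mask(self) -> np.ndarray:
        """Values at in-mask cells, 1-D."""
        return self.values[self.grid.study_mask]

    def copy(self, **updates) -> "ScoredLayer":
        kw = dict(grid=self.grid, values=self.values.copy(),
                  name=self.name, provenance=self.provenance)
        kw.update(updates)
        return ScoredLayer(**kw)


def full_layer(grid: PlanningGrid, value: float = 1.0, name: str = "",
               provenance: str = "") -> ScoredLayer:
    """A layer holding a constant score at every in-mask cell."""
    vals = np.full(grid.shape, float(value))
    vals[~grid.study_mask] = np.nan
    return ScoredLayer(grid, vals, name=name, provenance=provenance)
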