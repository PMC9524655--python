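"""Statutory vulnerability rubric and per-species scored layers.

The rubric converts a species' statutory listing (ESA or MMPA), listing
status, population trend and population-size class into a single
suitability score between 0.1 (most vulnerable — ESA Endangered with a
declining and/or small population) and 0.8 (least vulnerable — an MMPA
stock with a large population).  "Small population" means 500
individuals or fewer.  Within a species' spatial footprint every grid
cell takes the rubric score; everywhere else the species contributes a 1
(no conflict).

The rubric ships as an editable CSV (``data/vulnerability_rubric.csv``)
so the scoring can be re-parameterized for other jurisdictions.  Rows
use ``|``-separated alternatives and ``*`` wildcards; a query matching
no row is an error — the rubric never silently defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .geometry import rasterize_polygons
from .grid import PlanningGrid, ScoredLayer

STATUTES = frozenset({"ESA", "MMPA"})
STATUSES = frozenset({"Endangered", "Threatened", "Strategic", "Listed"})
TRENDS = frozenset({"declining", "stable", "increasing", "unknown"})
POPULATION_CLASSES = frozenset({"small", "large", "unspecified"})

#: "small population" cutoff, individuals
SMALL_POPULATION_MAX = 500

#: generalized score reserved for areas needing further consideration
NEEDS_CONSIDERATION_SCORE = 0.5


@dataclass(frozen=True)
class VulnerabilityRecord:
    """One species/stock with its statutory classification and the
    rubric score derived from it."""

    species: str
    statute: str
    status: str
    trend: str
    population_class: str = "unspecified"
    score: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.score is None:
            object.__setattr__(
                self,
                "score",
                score_from_rubric(self.statute, self.status, self.trend,
                                  self.population_class),
            )


class Rubric:
    """A loaded scoring table mapping (statute, status, trend,
    population_class) to a score."""

    def __init__(self, table: pd.DataFrame):
        required = {"statute", "status", "trend", "population_class", "score"}
        if missing := required - set(table.columns):
            raise ValueError(f"rubric table lacks columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def default(cls) -> "Rubric":
        with resources.files("seaplan.data").joinpath(
            "vulnerability_rubric.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Rubric":
        return cls(pd.read_csv(path))

    @staticmethod
    def _matches(cell: str, value: str) -> bool:
        return cell.strip() == "*" or value in {
            t.strip() for t in str(cell).split("|")
        }

    def score(self, statute: str, status: str, trend: str,
              population_class: str = "unspecified") -> float:
        if statute not in STATUTES:
            raise ValueError(f"unknown statute {statute!r}; expected one of "
                             f"{sorted(STATUTES)}")
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        if trend not in TRENDS:
            raise ValueError(f"unknown trend {trend!r}")
        if population_class not in POPULATION_CLASSES:
            raise ValueError(f"unknown population class {population_class!r}")
        for row in self.table.itertuples(index=False):
            if (
                row.statute == statute
                and row.status == status
                and self._matches(row.trend, trend)
                and self._matches(row.population_class, population_class)
            ):
                return float(row.score)
        raise LookupError(
            f"no rubric row covers ({statute}, {status}, {trend}, "
            f"{population_class}); the rubric never defaults — add a row "
            "if this combination is meaningful"
        )


_DEFAULT_RUBRIC: Rubric | None = None


def _default_rubric() -> Rubric:
    global _DEFAULT_RUBRIC
    if _DEFAULT_RUBRIC is None:
        _DEFAULT_RUBRIC = Rubric.default()
    return _DEFAULT_RUBRIC


def score_from_rubric(statute: str, status: str, trend: str,
                      population_class: str = "unspecified",
                      rubric: Rubric | None = None) -> float:
    """Rubric score for one (statute, status, trend, population_class).

    Examples
    --------
    >>> score_from_rubric("ESA", "Endangered", "declining", "small")
    0.1
    >>> score_from_rubric("ESA", "Threatened", "increasing")
    0.5
    """
    return (rubric or _default_rubric()).score(
        statute, status, trend, population_class
    )


def build_species_layer(grid: PlanningGrid, footprint_polygons,
                        record: VulnerabilityRecord,
                        rule: str = "center") -> ScoredLayer:
    """Scored layer for one species: footprint cells take the record's
    rubric score, every other in-mask cell takes 1.

    The footprint may be the union of several derivations (high-use
    area + migratory corridor; core + extended habitat).  A footprint
    entirely outside the grid yields an all-1 layer with a warning.
    """
    layer = rasterize_polygons(
        footprint_polygons, grid,
        inside_value=record.score, outside_value=1.0,
        rule=rule, name=record.species,
    )
    from .geometry import _as_geom_list  # local import to avoid cycle noise

    if _as_geom_list(footprint_polygons) and not (
        (layer.values == record.score) & grid.study_mask
    ).any():
        warnings.warn(
            f"footprint for {record.species!r} covers no in-mask cell; "
            "layer is all ones",
            stacklevel=2,
        )
    layer.provenance = (
        f"{record.statute} {record.status}, trend {record.trend}, "
        f"population {record.population_class} -> score {record.score}"
    )
    return layer
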