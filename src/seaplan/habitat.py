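"""Species footprint derivation from heterogeneous occurrence data.

Protected-species data arrive in very different forms — encounter
databases, acoustic and satellite tag detections, aerial and fishery
observer sightings, and model prediction stacks.  This module turns each
form into a footprint polygon set by the corresponding rule:

* point clouds → truncated-kernel density surfaces (quartic kernel by
  default, matching the GIS kernel-density convention);
* density surfaces → high-use areas, either the upper two quartiles of
  positive-density cells or the smallest region holding a given
  fraction of the density mass (e.g. a 95% volume contour);
* residence locations → fixed-radius buffered discs;
* sparse sightings of very rare species → buffered convex hull trimmed
  to a maximum-depth isobath;
* monthly probability-of-occurrence stacks → per-cell maximum over
  months, thresholded at the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

from .geometry import BUFFER_QUAD_SEGS, buffer_points, cells_to_polygons
from .grid import PlanningGrid, ScoredLayer

DERIVATIONS = frozenset({
    "quartile_hua", "volume_contour", "buffered_residence",
    "buffered_hull", "corridor", "sdm_threshold",
})


class Bathymetry(NamedTuple):
    """Depth raster: positive depths in meters on a planning grid."""

    grid: PlanningGrid
    depth_m: np.ndarray


@dataclass
class DensitySurface:
    """Kernel density surface on a raster lattice (possibly finer than
    the planning grid).  ``values`` integrate to ``total_mass`` over the
    lattice (one unit of mass per input point)."""

    grid: PlanningGrid
    values: np.ndarray
    bandwidth_km: float
    kernel: str = "quartic"
    total_mass: float = 0.0

    @property
    def cell_mass(self) -> np.ndarray:
        return self.values * self.grid.cell_area_m2

    def mass(self) -> float:
        return float(np.nansum(self.cell_mass))


@dataclass
class HabitatPolygonSet:
    """Footprint polygons plus how they were derived."""

    polygons: BaseGeometry
    derivation: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.derivation not in DERIVATIONS:
            raise ValueError(f"unknown derivation {self.derivation!r}")


# ---------------------------------------------------------------------------
# kernel density
# ---------------------------------------------------------------------------

def _quartic(d: np.ndarray, r: float) -> np.ndarray:
    # unit-mass biweight kernel on a disc of radius r
    return 3.0 / (np.pi * r**2) * (1.0 - (d / r) ** 2) ** 2


def _gaussian(d: np.ndarray, r: float) -> np.ndarray:
    # truncated at r and renormalized to unit mass; sigma = r / 2
    sigma = r / 2.0
    norm = 2.0 * np.pi * sigma**2 * (1.0 - np.exp(-(r**2) / (2 * sigma**2)))
    return np.exp(-(d**2) / (2 * sigma**2)) / norm


_KERNELS = {"quartic": _quartic, "gaussian": _gaussian}


def density_raster_spec(points_xy: np.ndarray, search_radius_km: float,
                        cells_per_radius: int = 4) -> PlanningGrid:
    """Default density lattice: square cells of radius/``cells_per_radius``
    covering the points padded by one search radius."""
    xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    r = search_radius_km * 1000.0
    cell = r / cells_per_radius
    minx, miny = xy.min(axis=0) - r - cell
    maxx, maxy = xy.max(axis=0) + r + cell
    n_cols = int(np.ceil((maxx - minx) / cell))
    n_rows = int(np.ceil((maxy - miny) / cell))
    from .grid import ACRE_M2

    return PlanningGrid(
        n_rows=n_rows, n_cols=n_cols,
        cell_area_ac=cell * cell / ACRE_M2,
        origin=(minx, miny + n_rows * cell),
    )


def kernel_density(points_xy: np.ndarray, search_radius_km: float,
                   raster_spec: PlanningGrid | None = None,
                   kernel: str = "quartic") -> DensitySurface:
    """Truncated-kernel density surface from planar points.

    Each point contributes one unit of mass spread over a disc of the
    search radius, so the surface mass equals the number of points (to
    within the lattice discretization).
    """
    xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if xy.size == 0:
        raise ValueError("kernel density needs at least one point")
    if search_radius_km <= 0:
        raise ValueError("search radius must be positive")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    grid = raster_spec or density_raster_spec(xy, search_radius_km)
    r = search_radius_km * 1000.0
    if grid.cell_size > r:
        raise ValueError(
            "search radius is smaller than one raster cell; refine the "
            "density lattice"
        )
    gx, gy = grid.cell_centers()
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(centers)
    kfun = _KERNELS[kernel]
    vals = np.zeros(centers.shape[0])
    for px, py in xy:
        idx = tree.query_ball_point([px, py], r)
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.hypot(centers[idx, 0] - px, centers[idx, 1] - py)
        vals[idx] += kfun(d, r)
    return DensitySurface(
        grid=grid, values=vals.reshape(grid.shape),
        bandwidth_km=search_radius_km, kernel=kernel,
        total_mass=float(len(xy)),
    )


# ---------------------------------------------------------------------------
# high-use areas
# ---------------------------------------------------------------------------

def upper_quartile_hua(density: DensitySurface) -> HabitatPolygonSet:
    """Upper two quartiles of the positive-density cells, as polygons.

    Quartiles are taken over cells with positive density only; ties at
    the median are included.
    """
    vals = density.values
    positive = vals > 0
    if not positive.any():
        raise ValueError("density surface has no positive cells")
    med = float(np.median(vals[positive]))
    selected = positive & (vals >= med)
    return HabitatPolygonSet(
        polygons=cells_to_polygons(selected, density.grid),
        derivation="quartile_hua",
        params={"median_density": med,
                "bandwidth_km": density.bandwidth_km},
    )


def volume_contour(density: DensitySurface, level: float = 0.95
                   ) -> HabitatPolygonSet:
    """Smallest cell set (greedy by descending density) holding at
    least ``level`` of the surface mass — e.g. a 95% density contour."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    vals = density.values.ravel()
    mass = density.cell_mass.ravel()
    order = np.argsort(vals)[::-1]
    cum = np.cumsum(mass[order])
    total = cum[-1]
    if total <= 0:
        raise ValueError("density surface has no mass")
    k = int(np.searchsorted(cum, level * total)) + 1
    k = min(k, order.size)
    if k < order.size and vals[order[k - 1]] == vals[order[k]]:
        # the greedy cut falls inside a tie: the boundary is arbitrary
        warnings.warn(
            "density is flat across the contour boundary; returning a "
            "minimal superset of the requested mass level",
            stacklevel=2,
        )
    selected = np.zeros(vals.shape, dtype=bool)
    selected[order[:k]] = True
    return HabitatPolygonSet(
        polygons=cells_to_polygons(selected.reshape(density.grid.shape),
                                   density.grid),
        derivation="volume_contour",
        params={"level": level, "mass_fraction": float(cum[k - 1] / total)},
    )


# ---------------------------------------------------------------------------
# buffers and hulls
# ---------------------------------------------------------------------------

def buffered_residence_areas(points_xy: np.ndarray,
                             radius_km: float = 18.983) -> HabitatPolygonSet:
    """Union of fixed-radius discs around residence locations.

    The default 18.983 km radius makes an isolated residence area a
    disc of ~1,132 km², the mean size of published loggerhead 90/95%
    kernel home ranges.
    """
    xy = np.atleast_2d(np.asarray(points_xy, dtype=float)) \
        if np.size(points_xy) else np.empty((0, 2))
    return HabitatPolygonSet(
        polygons=buffer_points(xy, radius_km * 1000.0),
        derivation="buffered_residence",
        params={"radius_km": radius_km},
    )


def buffered_hull_habitat(points_xy: np.ndarray, bathymetry: Bathymetry,
                          buffer_km: float = 30.0,
                          max_depth_m: float = 410.0) -> HabitatPolygonSet:
    """Convex hull of sightings, buffered, then trimmed to the
    ``max_depth_m`` isobath (cells deeper than the cutoff are removed).

    Designed for very data-poor species where a hull that encompasses
    all detections is preferred over a density estimate.  Degenerate
    hulls (one point, collinear points) are handled: buffering a point
    or segment still yields a polygon.
    """
    xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if xy.size == 0:
        raise ValueError("hull habitat needs at least one point")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    buffered = hull.buffer(buffer_km * 1000.0, quad_segs=BUFFER_QUAD_SEGS) \
        if buffer_km > 0 else hull
    bgrid, depth = bathymetry.grid, np.asarray(bathymetry.depth_m, float)
    bx0, by0 = bgrid.origin
    bminx, bminy = bx0, by0 - bgrid.n_rows * bgrid.cell_size
    bmaxx, bmaxy = bx0 + bgrid.n_cols * bgrid.cell_size, by0
    minx, miny, maxx, maxy = buffered.bounds
    if minx < bminx or miny < bminy or maxx > bmaxx or maxy > bmaxy:
        raise ValueError("bathymetry raster does not cover the buffered hull")
    shallow = cells_to_polygons(depth <= max_depth_m, bgrid)
    trimmed = buffered.intersection(shallow)
    return HabitatPolygonSet(
        polygons=trimmed,
        derivation="buffered_hull",
        params={"buffer_km": buffer_km, "max_depth_m": max_depth_m,
                "n_points": int(len(xy))},
    )


# ---------------------------------------------------------------------------
# SDM stack thresholding
# ---------------------------------------------------------------------------

def sdm_threshold_layer(prob_stack: Sequence[np.ndarray] | np.ndarray,
                        grid: PlanningGrid,
                        hua_score: float = 0.4,
                        name: str = "sdm_hua") -> ScoredLayer:
    """High-use layer from a stack of monthly occurrence-probability
    rasters: per-cell maximum over months, scored ``hua_score`` where
    the maximum exceeds the in-mask median, 1 elsewhere.

    NaN months are skipped per cell; a cell with no finite month falls
    outside the mask.
    """
    stack = np.asarray(prob_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("probability stack must hold at least one month")
    if stack.shape[1:] != grid.shape:
        raise ValueError("stack shape does not match grid")
    finite = np.isfinite(stack)
    if np.any(stack[finite] < 0) or np.any(stack[finite] > 1):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        max_prob = np.nanmax(stack, axis=0)
    valid = grid.study_mask & np.isfinite(max_prob)
    if not valid.any():
        raise ValueError("no cell has a finite occurrence probability")
    med = float(np.median(max_prob[valid]))
    vals = np.where(valid & (max_prob > med), hua_score, 1.0)
    vals[~valid] = np.nan
    layer = ScoredLayer(grid, vals, name=name)
    layer.provenance = (
        f"max over {stack.shape[0]} monthly predictions, median cutoff "
        f"{med:.4g}, HUA score {hua_score}"
    )
    return layer
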