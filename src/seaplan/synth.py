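"""Synthetic study systems for exercising the full siting pipeline.

Three generators, all fully deterministic under a fixed seed:

* ``hypothetical_fixture`` — the three-species teaching landscape (a
  geographically constricted endangered species scored 0.1, a broadly
  distributed declining threatened species scored 0.4, and a broadly
  distributed large-population marine mammal scored 0.8) with every
  overlap combination present;
* ``random_landscape`` — blob-shaped footprints from thresholded
  smoothed noise, for property tests;
* ``synthetic_gulf`` — a miniature four-subregion shelf: depth-banded
  study area, eight species layers built through the real habitat
  derivations (hull + isobath trim, kernel densities, volume contour,
  residence buffers, corridor unions, SDM stack threshold), four
  generic submodel layers, a constraints mask that fully blocks one
  subregion, inlet points and relative-use criteria rasters.  A
  low-conflict corridor is planted in the West subregion, large enough
  for a 14x14-cell parcel, and is by construction the suitability
  optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import cells_to_polygons
from .grid import PlanningGrid, ScoredLayer, full_layer
from .habitat import (
    Bathymetry,
    buffered_hull_habitat,
    buffered_residence_areas,
    kernel_density,
    sdm_threshold_layer,
    upper_quartile_hua,
    volume_contour,
)
from .scoring import VulnerabilityRecord, build_species_layer

SUBREGIONS = ("West", "Central", "East", "Southeast")


# ---------------------------------------------------------------------------
# hypothetical three-species landscape
# ---------------------------------------------------------------------------

def hypothetical_fixture(grid: PlanningGrid) -> list[ScoredLayer]:
    """Three-species teaching landscape on any grid of at least 20x20.

    Returns layers scored 0.1 (compact ~10% patch), 0.4 and 0.8
    (overlapping ~60% swaths).  The column bands guarantee cells with
    no species, only the 0.4 species, only the 0.8 species, the pair,
    and all three.
    """
    R, C = grid.shape
    if R < 20 or C < 20:
        raise ValueError("hypothetical fixture needs a grid of at least 20x20")

    sp2 = np.zeros(grid.shape, dtype=bool)   # broad, cols [0, 0.60C)
    sp2[:, : int(0.60 * C)] = True
    sp3 = np.zeros(grid.shape, dtype=bool)   # broad, cols [0.25C, 0.85C)
    sp3[:, int(0.25 * C): int(0.85 * C)] = True
    sp1 = np.zeros(grid.shape, dtype=bool)   # compact ~10% patch inside both
    h = max(2, int(round(np.sqrt(0.10 * R * C))))
    r0 = (R - h) // 2
    c0 = int(0.30 * C)
    sp1[r0: r0 + h, c0: c0 + min(h, int(0.55 * C) - c0)] = True

    def _layer(mask: np.ndarray, score: float, name: str) -> ScoredLayer:
        vals = np.where(mask, score, 1.0)
        vals[~grid.study_mask] = np.nan
        return ScoredLayer(grid, vals, name=name)

    return [
        _layer(sp1, 0.1, "species_1_constricted_endangered"),
        _layer(sp2, 0.4, "species_2_broad_threatened"),
        _layer(sp3, 0.8, "species_3_broad_mammal"),
    ]


# ---------------------------------------------------------------------------
# random blob landscapes
# ---------------------------------------------------------------------------

def _blob_mask(rng: np.random.Generator, grid: PlanningGrid,
               occupancy: float, sigma: float = 3.0) -> np.ndarray:
    """Smoothed-noise footprint covering ``occupancy`` of the in-mask
    cells (threshold at the matching quantile of the smoothed field)."""
    field_ = ndimage.gaussian_filter(
        rng.random(grid.shape), sigma=sigma, mode="nearest"
    )
    inside = grid.study_mask
    if occupancy <= 0:
        return np.zeros(grid.shape, dtype=bool)
    thresh = np.quantile(field_[inside], 1.0 - occupancy)
    return inside & (field_ > thresh)


def random_landscape(seed: int, grid: PlanningGrid, n_species: int,
                     scores, occupancy) -> list[ScoredLayer]:
    """Reproducible blob-footprint layers; ``scores`` and ``occupancy``
    may be scalars or per-species sequences."""
    rng = np.random.default_rng(seed)
    scores = np.broadcast_to(np.asarray(scores, dtype=float), (n_species,))
    occ = np.broadcast_to(np.asarray(occupancy, dtype=float), (n_species,))
    layers = []
    for k in range(n_species):
        mask = _blob_mask(rng, grid, occ[k])
        vals = np.where(mask, scores[k], 1.0)
        vals[~grid.study_mask] = np.nan
        layers.append(ScoredLayer(grid, vals, name=f"species_{k + 1}"))
    return layers


# ---------------------------------------------------------------------------
# miniature four-subregion study area
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """Everything the end-to-end pipeline consumes, generated in
    memory."""

    seed: int
    grid: PlanningGrid
    bathymetry: Bathymetry
    species_layers: list[ScoredLayer]
    species_records: list[VulnerabilityRecord]
    submodel_layers: dict[str, list[ScoredLayer]]
    constraints_excluded: np.ndarray
    inlets_xy: np.ndarray
    fishing_effort: np.ndarray
    vessel_traffic: np.ndarray
    oceanographic: np.ndarray
    corridor_mask: np.ndarray
    blocked_subregion: str = "Southeast"
    notes: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, sigma=4.0,
                  lo=0.0, hi=1.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.random(shape), sigma=sigma,
                                mode="nearest")
    f = (f - f.min()) / (f.max() - f.min())
    return lo + f * (hi - lo)


def synthetic_gulf(seed: int = 0, n_rows: int = 40, n_cols: int = 120,
                   cell_area_ac: float = 40.0) -> SyntheticScenario:
    """Build the miniature shelf scenario.

    Four equal column-band subregions (West, Central, East, Southeast);
    depth increases offshore (southward) and the study area is the
    50-150 m band; the Southeast band is fully blocked by constraints;
    a low-conflict corridor holding a 14x14-cell block is planted in
    the West band.
    """
    rng = np.random.default_rng(seed)
    band = n_cols // 4
    sub_id = np.repeat(np.arange(4), band)[None, :] * np.ones(
        (n_rows, 1), dtype=int
    )
    sub_id = sub_id[:, :n_cols].astype(int)

    # synthetic shelf: shallow in the north, deepening offshore
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    depth = 30.0 + 3.5 * rows + 4.0 * np.sin(cols / 9.0)
    mask = (depth >= 50.0) & (depth <= 150.0)

    grid = PlanningGrid(
        n_rows=n_rows, n_cols=n_cols, cell_area_ac=cell_area_ac,
        origin=(0.0, n_rows * np.sqrt(cell_area_ac * 4046.8564224)),
        subregion_id=sub_id, subregion_names=SUBREGIONS, study_mask=mask,
    )
    s = grid.cell_size
    bathy = Bathymetry(grid=grid, depth_m=depth)

    def cell_xy(r, c):
        x0, y0 = grid.origin
        return (x0 + (c + 0.5) * s, y0 - (r + 0.5) * s)

    in_rows = np.nonzero(mask.any(axis=1))[0]
    r_lo, r_hi = int(in_rows.min()), int(in_rows.max())

    # planted low-conflict corridor in the West band: 16x16 cells
    corridor = np.zeros(grid.shape, dtype=bool)
    cr0 = r_lo + 3
    cc0 = 6
    corridor[cr0: cr0 + 16, cc0: cc0 + 16] = True
    corridor &= mask

    km = 1000.0 / s  # cells per km

    def pts(row_col_pairs):
        return np.array([cell_xy(r, c) for r, c in row_col_pairs])

    # --- species footprints through the habitat derivations ------------
    records = [
        VulnerabilityRecord("whale_analog", "ESA", "Endangered",
                            "declining", "small"),
        VulnerabilityRecord("leatherback_analog", "ESA", "Endangered",
                            "declining"),
        VulnerabilityRecord("kemps_analog", "ESA", "Endangered", "unknown"),
        VulnerabilityRecord("hawksbill_analog", "ESA", "Endangered",
                            "unknown"),
        VulnerabilityRecord("sawfish_analog", "ESA", "Endangered",
                            "increasing"),
        VulnerabilityRecord("manta_analog", "ESA", "Threatened", "declining"),
        VulnerabilityRecord("loggerhead_analog", "ESA", "Threatened",
                            "unknown"),
        VulnerabilityRecord("green_analog", "ESA", "Threatened",
                            "increasing"),
    ]
    layers: list[ScoredLayer] = []

    # 1. data-poor whale analog: buffered hull trimmed to a synthetic isobath
    whale_pts = pts([(r_lo + 4 + int(rng.integers(0, 10)),
                      64 + int(rng.integers(0, 18))) for _ in range(9)])
    hull = buffered_hull_habitat(whale_pts, bathy, buffer_km=1.5,
                                 max_depth_m=140.0)
    layers.append(build_species_layer(grid, hull.polygons, records[0]))

    # 2. aerial-survey KDE, upper-two-quartile high-use area
    aer = pts([(r_lo + int(rng.integers(0, r_hi - r_lo)),
                34 + int(rng.integers(0, 22))) for _ in range(60)])
    dens = kernel_density(aer, search_radius_km=2.0)
    hua = upper_quartile_hua(dens)
    layers.append(build_species_layer(grid, hua.polygons, records[1]))

    # 3. buffered residence areas
    res = pts([(r_lo + 6, 44), (r_lo + 10, 52), (r_hi - 4, 70)])
    resid = buffered_residence_areas(res, radius_km=2.0)
    layers.append(build_species_layer(grid, resid.polygons, records[2]))

    # 4. migratory corridor polygon (column band in the Southeast/East)
    corr_mask = np.zeros(grid.shape, dtype=bool)
    corr_mask[:, 88:94] = True
    corr_poly = cells_to_polygons(corr_mask & mask, grid)
    layers.append(build_species_layer(grid, corr_poly, records[3]))

    # 5. 95% volume contour on a pooled-point KDE
    saw = pts([(r_lo + 2 + int(rng.integers(0, 8)),
                96 + int(rng.integers(0, 20))) for _ in range(40)])
    saw_d = kernel_density(saw, search_radius_km=2.0)
    vc = volume_contour(saw_d, level=0.95)
    layers.append(build_species_layer(grid, vc.polygons, records[4]))

    # 6. SDM stack: 12 monthly probability fields, median cutoff
    stack = np.stack([
        _smooth_field(rng, grid.shape, sigma=5.0, lo=0.05, hi=0.95)
        for _ in range(12)
    ])
    manta = sdm_threshold_layer(stack, grid, hua_score=records[5].score,
                                name=records[5].species)
    layers.append(manta)

    # 7. union of a KDE high-use area and a migratory corridor
    log_pts = pts([(r_lo + int(rng.integers(0, r_hi - r_lo)),
                    50 + int(rng.integers(0, 30))) for _ in range(50)])
    log_hua = upper_quartile_hua(kernel_density(log_pts, search_radius_km=2.0))
    log_corr = np.zeros(grid.shape, dtype=bool)
    log_corr[:, 80:84] = True
    union = [log_hua.polygons, cells_to_polygons(log_corr & mask, grid)]
    layers.append(build_species_layer(grid, union, records[6]))

    # 8. blob footprint
    green_mask = _blob_mask(rng, grid, occupancy=0.25, sigma=4.0)
    vals = np.where(green_mask, records[7].score, 1.0)
    vals[~mask] = np.nan
    layers.append(ScoredLayer(grid, vals, name=records[7].species))

    # plant the corridor: no species footprint intersects it
    for lyr in layers:
        lyr.values[corridor] = 1.0

    # --- generic submodel layers --------------------------------------
    def blob_layer(occ, score, name):
        m = _blob_mask(rng, grid, occupancy=occ, sigma=5.0)
        m &= ~corridor
        v = np.where(m, score, 1.0)
        v[~mask] = np.nan
        return ScoredLayer(grid, v, name=name)

    fishing_effort = _smooth_field(rng, grid.shape, sigma=5.0, lo=0.1, hi=1.0)
    vessel_traffic = _smooth_field(rng, grid.shape, sigma=5.0, lo=0.1, hi=1.0)
    oceanographic = _smooth_field(rng, grid.shape, sigma=6.0, lo=0.2, hi=0.8)
    fishing_effort[corridor] *= 0.1
    vessel_traffic[corridor] *= 0.1

    fish_vals = 1.0 - 0.5 * fishing_effort
    fish_vals[~mask] = np.nan

    submodels = {
        "national_security": [blob_layer(0.2, 0.5, "military_zones")],
        "industry_nav_transport": [blob_layer(0.25, 0.5, "vessel_corridors")],
        "fishing_aquaculture": [
            ScoredLayer(grid, fish_vals, name="relative_fishing_effort")
        ],
        # natural_cultural gets the sanctuary layer here; the combined
        # species layer is appended by the pipeline
        "natural_cultural": [blob_layer(0.05, 0.5, "sanctuary")],
    }

    # --- constraints: Southeast fully blocked + scattered exclusions ---
    excluded = _blob_mask(rng, grid, occupancy=0.08, sigma=2.5)
    excluded &= ~corridor
    excluded |= (sub_id == SUBREGIONS.index("Southeast")) & mask
    excluded &= mask

    # inlets along the shallow (northern) study edge
    inlets = pts([(r_lo, cc0 + 8), (r_lo, 45), (r_lo, 75), (r_lo, 100)])

    return SyntheticScenario(
        seed=seed, grid=grid, bathymetry=bathy,
        species_layers=layers, species_records=records,
        submodel_layers=submodels, constraints_excluded=excluded,
        inlets_xy=inlets, fishing_effort=fishing_effort,
        vessel_traffic=vessel_traffic, oceanographic=oceanographic,
        corridor_mask=corridor,
        notes={"corridor_block": (cr0, cc0, 16)},
    )
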