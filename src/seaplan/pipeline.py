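"""Config-driven orchestration of the full siting pipeline.

Stages: combine species layers → assemble submodels and the
constraint-masked geometric-mean suitability surface → LISA cluster
detection → two-stage TOPSIS precision siting → conflict matrix.  A
single YAML config names every input and parameter; one seed drives all
randomness, and a rerun with the same config and seed reproduces every
artifact bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from shapely.geometry import box

from . import __version__
from .combine import CombinedLayer, MethodComparison, combine_layers, compare_methods
from .grid import PlanningGrid, ScoredLayer
from .io import (
    read_ascii_grid,
    read_grid,
    read_layer,
    write_ascii_grid,
    write_geojson,
    write_grid,
)
from .siting import (
    DEFAULT_SIZES_AC,
    ConflictReport,
    LisaResult,
    SitingOption,
    attach_criteria,
    conflict_matrix,
    fit_square_options,
    local_morans,
    rank_two_stage,
    select_final_options,
    significant_clusters,
)
from .suitability import (
    SuitabilitySurface,
    assemble_submodel,
    constraints_submodel,
    cumulative_model,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class DerivationParams(BaseModel):
    """Species-footprint derivation defaults (all lengths km unless
    noted): kernel search radii per point source, residence-buffer
    radius, hull buffer, isobath trim depth (m), and the volume-contour
    level."""

    model_config = ConfigDict(extra="forbid")

    kde_radius_telemetry_km: float = 19.0
    kde_radius_observer_km: float = 19.0
    kde_radius_aerial_km: float = 40.0
    residence_buffer_km: float = 18.983
    hull_buffer_km: float = 30.0
    isobath_trim_m: float = 410.0
    volume_contour_level: float = 0.95


class LisaParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scheme: str = "queen"
    permutations: int = 999
    alpha: float = 0.05
    seed: int = 0


class SitingParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sizes_ac: list[float] = list(DEFAULT_SIZES_AC)
    per_subregion: int = 3
    use_oceanographic: bool = True


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    grid: str = "grid.json"
    species_dir: str = "species"
    submodels: dict[str, list[str]] = {}
    constraints: str = "constraints.asc"
    inlets: str = "inlets.csv"
    fishing_effort: str = "criteria/fishing_effort.asc"
    vessel_traffic: str = "criteria/vessel_traffic.asc"
    oceanographic: str | None = None
    combination_method: str = "product"
    rubric: str | None = None
    derivation: DerivationParams = DerivationParams()
    lisa: LisaParams = LisaParams()
    siting: SitingParams = SitingParams()
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    grid: PlanningGrid
    species_layers: list[ScoredLayer]
    submodel_layers: dict[str, list[ScoredLayer]]
    excluded: np.ndarray
    inlets_xy: np.ndarray
    fishing_effort: np.ndarray
    vessel_traffic: np.ndarray
    oceanographic: np.ndarray | None


def load_inputs(cfg: PipelineConfig, base: str | Path) -> PipelineInputs:
    base = Path(base)
    grid = read_grid(base / cfg.grid)
    species = [
        read_layer(p, grid)
        for p in sorted((base / cfg.species_dir).glob("*.asc"))
    ]
    if not species:
        raise FileNotFoundError(
            f"no species layers (*.asc) under {base / cfg.species_dir}"
        )
    submodels = {
        name: [read_layer(base / p, grid) for p in paths]
        for name, paths in cfg.submodels.items()
    }
    cons_vals, _ = read_ascii_grid(base / cfg.constraints)
    excluded = (cons_vals == 0.0) & grid.study_mask
    inlets = pd.read_csv(base / cfg.inlets)[["x", "y"]].to_numpy(float)
    fishing, _ = read_ascii_grid(base / cfg.fishing_effort)
    vessel, _ = read_ascii_grid(base / cfg.vessel_traffic)
    ocean = None
    if cfg.oceanographic:
        ocean, _ = read_ascii_grid(base / cfg.oceanographic)
    return PipelineInputs(
        grid=grid, species_layers=species, submodel_layers=submodels,
        excluded=excluded, inlets_xy=inlets, fishing_effort=fishing,
        vessel_traffic=vessel, oceanographic=ocean,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_combine(inputs: PipelineInputs, method: str
                  ) -> tuple[CombinedLayer, MethodComparison]:
    combined = combine_layers(inputs.species_layers, method)
    comparison = compare_methods(inputs.species_layers)
    return combined, comparison


def stage_suitability(inputs: PipelineInputs,
                      combined: CombinedLayer) -> SuitabilitySurface:
    species_layer = ScoredLayer(
        inputs.grid, combined.values, name="combined_protected_species",
        provenance=f"{combined.method} over {combined.n_layers} layers",
    )
    submodels = []
    for name, members in inputs.submodel_layers.items():
        if name == "natural_cultural":
            members = list(members) + [species_layer]
        submodels.append(assemble_submodel(name, members))
    cons = constraints_submodel(inputs.grid, inputs.excluded)
    return cumulative_model(submodels, cons)


def stage_cluster(surface: SuitabilitySurface, lisa_cfg: LisaParams
                  ) -> tuple[LisaResult, np.ndarray]:
    lisa = local_morans(
        surface, scheme=lisa_cfg.scheme,
        permutations=lisa_cfg.permutations, seed=lisa_cfg.seed,
    )
    clusters = significant_clusters(lisa, alpha=lisa_cfg.alpha)
    return lisa, clusters


def stage_site(inputs: PipelineInputs, surface: SuitabilitySurface,
               clusters: np.ndarray, siting_cfg: SitingParams
               ) -> list[SitingOption]:
    grid = inputs.grid
    min_side_ok = []
    options_by_cluster: dict[int, list[SitingOption]] = {}
    for cid in range(1, int(clusters.max()) + 1):
        opts = fit_square_options(clusters, cid, grid,
                                  sizes_ac=siting_cfg.sizes_ac)
        # exclude any parcel touching a constraint cell
        opts = [o for o in opts
                if not inputs.excluded[o.footprint(grid.shape)].any()]
        if opts:
            options_by_cluster[cid] = opts
            min_side_ok.append(cid)
    all_opts = [o for v in options_by_cluster.values() for o in v]
    use_ocean = siting_cfg.use_oceanographic and inputs.oceanographic is not None
    attach_criteria(
        all_opts, grid, inputs.inlets_xy, inputs.fishing_effort,
        inputs.vessel_traffic,
        inputs.oceanographic if use_ocean else None,
    )
    ranked = rank_two_stage(options_by_cluster, use_oceanographic=use_ocean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return select_final_options(ranked, siting_cfg.per_subregion)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    combined: CombinedLayer
    comparison: MethodComparison
    surface: SuitabilitySurface
    lisa: LisaResult
    clusters: np.ndarray
    final_options: list[SitingOption]
    conflicts: ConflictReport
    out_dir: Path


def options_to_geojson(options: list[SitingOption], grid: PlanningGrid,
                       path: str | Path) -> None:
    geoms, props = [], []
    for o in options:
        r0, c0, s = o.row0, o.col0, o.side
        minx, miny, _, _ = grid.cell_bounds(r0 + s - 1, c0)
        _, _, maxx, maxy = grid.cell_bounds(r0, c0 + s - 1)
        geoms.append(box(minx, miny, maxx, maxy))
        props.append({
            "option_id": o.option_id, "subregion": o.subregion,
            "cluster_id": o.cluster_id, "size_class_ac": o.size_class_ac,
            "side_cells": o.side, "row0": o.row0, "col0": o.col0,
            "topsis_closeness": o.topsis_closeness,
            "within_cluster_rank": o.within_cluster_rank,
            "final_rank": o.final_rank, **o.criteria,
        })
    write_geojson(geoms, path, props)


def run_pipeline(cfg: PipelineConfig, base_dir: str | Path,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage, persisting each intermediate under the output
    directory, and return the in-memory results."""
    base = Path(base_dir)
    out = Path(out_dir) if out_dir else base / cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    inputs = load_inputs(cfg, base)
    grid = inputs.grid

    stage = "combine"
    try:
        combined, comparison = stage_combine(inputs, cfg.combination_method)
        write_ascii_grid(combined.values, grid, out / "combined_species.asc")
        comparison.spread.to_csv(out / "method_spread.csv")
        comparison.disagreement.to_csv(out / "method_disagreement.csv",
                                       index=False)

        stage = "suitability"
        surface = stage_suitability(inputs, combined)
        write_ascii_grid(surface.values, grid, out / "suitability.asc")

        stage = "cluster"
        lisa, clusters = stage_cluster(surface, cfg.lisa)
        write_ascii_grid(clusters.astype(float), grid, out / "clusters.asc")
        write_ascii_grid(lisa.p_value, grid, out / "lisa_p.asc")

        stage = "site"
        final = stage_site(inputs, surface, clusters, cfg.siting)
        options_to_geojson(final, grid, out / "options.geojson")

        stage = "conflicts"
        report = conflict_matrix(final, inputs.species_layers)
        report.table.to_csv(out / "conflict_matrix.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    log = {
        "seaplan_version": __version__,
        "seed": cfg.seed,
        "lisa": cfg.lisa.model_dump(),
        "siting": cfg.siting.model_dump(),
        "combination_method": cfg.combination_method,
        "n_species_layers": len(inputs.species_layers),
        "n_clusters": int(clusters.max()),
        "n_final_options": len(final),
        "total_pairs": report.total_pairs if final else 0,
        "n_conflicts": report.n_conflicts if final else 0,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return PipelineResult(
        combined=combined, comparison=comparison, surface=surface,
        lisa=lisa, clusters=clusters, final_options=final,
        conflicts=report, out_dir=out,
    )


# ---------------------------------------------------------------------------
# scenario serialization (synth -> directory of text inputs)
# ---------------------------------------------------------------------------

def scenario_to_directory(scenario, path: str | Path) -> PipelineConfig:
    """Write a SyntheticScenario as a pipeline-consumable directory of
    text inputs plus a config.yaml; returns the config."""
    base = Path(path)
    (base / "species").mkdir(parents=True, exist_ok=True)
    (base / "criteria").mkdir(exist_ok=True)
    grid = scenario.grid
    write_grid(grid, base / "grid.json")
    write_ascii_grid(scenario.bathymetry.depth_m, grid,
                     base / "bathymetry.asc")
    for k, lyr in enumerate(scenario.species_layers):
        write_ascii_grid(lyr.values, grid,
                         base / "species" / f"{k:02d}_{lyr.name}.asc")
    submodel_paths: dict[str, list[str]] = {}
    for name, members in scenario.submodel_layers.items():
        d = base / "submodels" / name
        d.mkdir(parents=True, exist_ok=True)
        paths = []
        for lyr in members:
            p = d / f"{lyr.name}.asc"
            write_ascii_grid(lyr.values, grid, p)
            paths.append(str(p.relative_to(base)))
        submodel_paths[name] = paths
    cons = np.where(scenario.constraints_excluded, 0.0, 1.0)
    cons[~grid.study_mask] = np.nan
    write_ascii_grid(cons, grid, base / "constraints.asc")
    for name, arr in [("fishing_effort", scenario.fishing_effort),
                      ("vessel_traffic", scenario.vessel_traffic),
                      ("oceanographic", scenario.oceanographic)]:
        write_ascii_grid(arr, grid, base / "criteria" / f"{name}.asc")
    pd.DataFrame(scenario.inlets_xy, columns=["x", "y"]).to_csv(
        base / "inlets.csv", index=False
    )
    cfg = PipelineConfig(
        seed=scenario.seed,
        submodels=submodel_paths,
        oceanographic="criteria/oceanographic.asc",
        lisa=LisaParams(seed=scenario.seed),
    )
    cfg.to_yaml(base / "config.yaml")
    return cfg
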