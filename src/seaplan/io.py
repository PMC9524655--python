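"""Readers and writers for the text formats the toolkit exchanges.

Rasters travel as single-band ESRI ASCII grids (``.asc``) or as a
``row,col,value`` CSV dialect; vector footprints as GeoJSON; point
observations as CSV with an ``x,y,source,species[,timestamp]`` header;
grid definitions as JSON.  All coordinates are planar (projected CRS,
meters) — geographic inputs must be projected upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import POINT_SOURCES, PlanningGrid, ScoredLayer

NODATA = -9999.0


# ---------------------------------------------------------------------------
# grid spec
# ---------------------------------------------------------------------------

def write_grid(grid: PlanningGrid, path: str | Path) -> None:
    spec = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_area_ac": float(grid.cell_area_ac),
        "origin": [float(v) for v in grid.origin],
        "subregion_names": list(grid.subregion_names),
        "subregion_id": None if grid.subregion_id is None
        else grid.subregion_id.tolist(),
        "study_mask": grid.study_mask.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(spec))


def read_grid(path: str | Path) -> PlanningGrid:
    spec = json.loads(Path(path).read_text())
    sub = spec.get("subregion_id")
    return PlanningGrid(
        n_rows=spec["n_rows"],
        n_cols=spec["n_cols"],
        cell_area_ac=spec["cell_area_ac"],
        origin=tuple(spec["origin"]),
        subregion_id=None if sub is None else np.asarray(sub, dtype=int),
        subregion_names=tuple(spec.get("subregion_names", ())),
        study_mask=np.asarray(spec["study_mask"], dtype=bool),
    )


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_ascii_grid(values: np.ndarray, grid: PlanningGrid,
                     path: str | Path) -> None:
    """Write a float array as a single-band ESRI ASCII grid.

    NaN cells are written as the nodata sentinel.  Values are written in
    full ``repr`` precision so a write/read round trip is bit-exact.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    x0, y0 = (float(v) for v in grid.origin)
    s = float(grid.cell_size)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {x0!r}",
        f"yllcorner {y0 - grid.n_rows * s!r}",
        f"cellsize {s!r}",
        f"NODATA_value {NODATA!r}",
    ]
    out = np.where(np.isnan(vals), NODATA, vals)
    for row in out:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid into ``(values, header)``; nodata → NaN."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(text[i:], dtype=float, ndmin=2)
    nodata = header.get("nodata_value", NODATA)
    vals[vals == nodata] = np.nan
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data block does not match declared shape")
    return vals, header


def write_layer(layer: ScoredLayer, path: str | Path) -> None:
    """Write a ScoredLayer as ``.asc`` or ``(row,col,value)`` CSV by
    file extension."""
    path = Path(path)
    if path.suffix == ".csv":
        rows, cols = np.nonzero(~np.isnan(layer.values))
        pd.DataFrame({
            "row": rows, "col": cols,
            "value": layer.values[rows, cols],
        }).to_csv(path, index=False, float_format="%.17g")
    else:
        write_ascii_grid(layer.values, layer.grid, path)


def read_layer(path: str | Path, grid: PlanningGrid, name: str = "",
               provenance: str = "") -> ScoredLayer:
    """Read a score raster (``.asc`` or ``row,col,value`` CSV) aligned
    to *grid*.

    No-data cells are mapped outside the mask (NaN).  Raises on a shape
    mismatch or on values outside ``(0, 1]``.
    """
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"row", "col", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: grid CSV lacks columns {sorted(missing)}")
        vals = np.full(grid.shape, np.nan)
        r = df["row"].to_numpy(int)
        c = df["col"].to_numpy(int)
        if r.size and (r.min() < 0 or r.max() >= grid.n_rows
                       or c.min() < 0 or c.max() >= grid.n_cols):
            raise ValueError(f"{path}: cell indices fall outside the grid")
        vals[r, c] = df["value"].to_numpy(float)
    else:
        vals, header = read_ascii_grid(path)
        if vals.shape != grid.shape:
            raise ValueError(
                f"{path}: raster shape {vals.shape} does not align with "
                f"grid shape {grid.shape}"
            )
        if "cellsize" in header and not np.isclose(
            header["cellsize"], grid.cell_size, rtol=1e-6
        ):
            raise ValueError(f"{path}: raster cell size does not match grid")
    vals = np.where(grid.study_mask, vals, np.nan)
    return ScoredLayer(grid, vals, name=name or path.stem, provenance=provenance)


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

def write_geojson(geoms: list[BaseGeometry], path: str | Path,
                  properties: list[dict] | None = None) -> None:
    props = properties or [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    data = json.loads(Path(path).read_text())
    if data.get("type") == "FeatureCollection":
        feats = data["features"]
    elif data.get("type") == "Feature":
        feats = [data]
    else:  # bare geometry
        return [shape(data)], [{}]
    geoms = [shape(f["geometry"]) for f in feats]
    props = [f.get("properties") or {} for f in feats]
    return geoms, props


# ---------------------------------------------------------------------------
# point tables
# ---------------------------------------------------------------------------

def read_points(path: str | Path) -> pd.DataFrame:
    """Read a point-observation CSV (``x,y,source,species[,timestamp]``).

    Coordinates must be finite planar meters; ``source`` must come from
    the closed vocabulary (encounter, acoustic, satellite, aerial,
    observer).
    """
    df = pd.read_csv(path)
    missing = {"x", "y", "source", "species"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: point CSV lacks columns {sorted(missing)}")
    xy = df[["x", "y"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise ValueError(f"{path}: non-finite coordinates")
    bad = set(df["source"].unique()) - POINT_SOURCES
    if bad:
        raise ValueError(
            f"{path}: unknown point sources {sorted(bad)}; expected one of "
            f"{sorted(POINT_SOURCES)}"
        )
    return df


def write_points(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
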