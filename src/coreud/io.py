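"""Plain-text readers/writers for the pipeline's tabular and spatial outputs.

Fixes and pseudo-tracks travel as CSV, haulouts and polygons as GeoJSON,
land masks and density grids as ESRI ASCII grids with JSON sidecars — all
text formats, all in projected planar km.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .simulate import HaulSite, Landscape
from .ud import DensityGrid

FIX_COLUMNS = ["animal_id", "time", "x_km", "y_km", "lc"]


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    cols = [c for c in fixes.columns if c in FIX_COLUMNS + ["true_x_km", "true_y_km"]]
    fixes.to_csv(path, index=False, columns=cols, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    df["lc"] = df["lc"].astype(str)
    return df


def write_pseudotrack_csv(ptrack, path) -> None:
    df = ptrack.df.copy()
    df["n_raw"] = ptrack.n_raw
    df["n_imputations"] = ptrack.n_imputations
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def write_haulouts_geojson(haulouts: list[HaulSite], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [h.x, h.y]},
            "properties": {"site_id": h.site_id, "kind": h.kind},
        }
        for h in haulouts
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_haulouts_geojson(path) -> list[HaulSite]:
    data = json.loads(Path(path).read_text())
    return [
        HaulSite(
            f["properties"]["site_id"],
            float(f["geometry"]["coordinates"][0]),
            float(f["geometry"]["coordinates"][1]),
            f["properties"].get("kind", "haulout"),
        )
        for f in data["features"]
    ]


def write_polygons_geojson(geom, path, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": properties or {},
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": [feature]})
    )


def _write_ascii_grid(values: np.ndarray, xll: float, yll: float,
                      cell: float, path, fmt: str = "%.10g") -> None:
    nrows, ncols = values.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {xll}\nyllcorner {yll}\n"
        f"cellsize {cell}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def _read_ascii_grid(path):
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        values = np.loadtxt(fh)
    values = values.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    return values, hdr


def write_landmask_ascii(landscape: Landscape, path) -> None:
    _write_ascii_grid(landscape.land.astype(int), landscape.xmin,
                      landscape.ymin, landscape.cell_size, path, fmt="%d")


def read_landmask_ascii(path, haulouts: list[HaulSite] | None = None) -> Landscape:
    values, hdr = _read_ascii_grid(path)
    return Landscape(hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
                     values.astype(bool), haulouts or [])


def write_density_grid(grid: DensityGrid, path_stem) -> None:
    """ASCII-grid raster plus a JSON sidecar with bandwidth/normalization."""
    stem = Path(path_stem)
    yll = grid.ymax - grid.nrows * grid.cell_size
    _write_ascii_grid(grid.values, grid.xmin, yll, grid.cell_size,
                      stem.with_suffix(".asc"))
    sidecar = {
        "bandwidth_km": grid.bandwidth,
        "n_points": grid.n_points,
        "cell_size_km": grid.cell_size,
        "integral": grid.integral(),
        "units": "probability density 1/km^2",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_density_grid(path_stem) -> DensityGrid:
    stem = Path(path_stem)
    values, hdr = _read_ascii_grid(stem.with_suffix(".asc"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    ymax = hdr["yllcorner"] + values.shape[0] * hdr["cellsize"]
    return DensityGrid(hdr["xllcorner"], ymax, hdr["cellsize"], values,
                       meta["bandwidth_km"], meta["n_points"])


def write_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
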