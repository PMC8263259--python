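"""Plain-text I/O: CSV tables, GeoJSON points, ESRI ASCII friction grids.

The friction grid is stored as an ESRI ASCII raster in a local projected
coordinate system (metres, origin at the grid's south-west corner) together
with a small JSON sidecar carrying the WGS84 georeference (corner lat/lon),
since the ASCII header alone cannot express a metric grid anchored at a
lat/lon corner.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geolink import FrictionSurface
from .readiness import ValidationError


def write_geojson_points(
    df: pd.DataFrame, path: str | Path, lat_col: str = "lat", lon_col: str = "lon"
) -> None:
    """Write a table with lat/lon columns as a GeoJSON FeatureCollection."""
    features = []
    prop_cols = [c for c in df.columns if c not in (lat_col, lon_col)]
    for _, row in df.iterrows():
        props = {}
        for c in prop_cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row[lon_col]), float(row[lat_col])],
                },
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_geojson_points(path: str | Path) -> pd.DataFrame:
    obj = json.loads(Path(path).read_text())
    rows = []
    for feat in obj["features"]:
        lon, lat = feat["geometry"]["coordinates"][:2]
        rows.append({**feat["properties"], "lat": lat, "lon": lon})
    return pd.DataFrame(rows)


def write_esri_ascii(surface: FrictionSurface, path: str | Path) -> None:
    """ESRI ASCII grid (local metres; inf cells become NODATA) + JSON sidecar."""
    path = Path(path)
    nrows, ncols = surface.shape
    nodata = -9999
    vals = np.where(np.isfinite(surface.values), surface.values, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {surface.cell_size_m}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in vals)
    path.write_text(header + body + "\n")
    sidecar = {
        "crs": "local equirectangular metres about grid mid-latitude",
        "lat0": surface.lat0,
        "lon0": surface.lon0,
        "cell_size_m": surface.cell_size_m,
        "nodata_is_barrier": True,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_esri_ascii(path: str | Path) -> FrictionSurface:
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(lines[i:], dtype=float)
    vals = np.atleast_2d(vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError("ESRI ASCII grid shape does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.inf, vals)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        lat0, lon0 = meta["lat0"], meta["lon0"]
        cell = meta.get("cell_size_m", header["cellsize"])
    else:
        lat0, lon0, cell = header["yllcorner"], header["xllcorner"], header["cellsize"]
    return FrictionSurface(lat0=lat0, lon0=lon0, cell_size_m=cell, values=vals)


def write_manifest(manifest: Mapping[str, Sequence[str]], path: str | Path) -> None:
    """Indicator manifest (domain -> indicator columns) as YAML."""
    Path(path).write_text(
        yaml.safe_dump({k: list(v) for k, v in manifest.items()}, sort_keys=False)
    )


def read_manifest(path: str | Path) -> dict[str, list[str]]:
    return yaml.safe_load(Path(path).read_text())


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
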