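"""Readers and writers for the pipeline's tables and geometries.

Tables travel as CSV with validated column schemas; site geometry as
GeoJSON; habitat rasters as plain-text ESRI ASCII grids; run
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import SIDES, AntennaGeometry
from .habitat import HabitatRaster

SCHEMAS = {
    "scans": ["timestamp_min", "individual_id", "antenna"]
    + [f"repeat_{i}" for i in range(1, 8)],
    "fixes": ["individual_id", "timestamp_min", "x", "y"],
    "captures": ["individual_id", "night", "trap", "x", "y"],
    "tests": [
        "individual_id",
        "sex",
        "site",
        "round",
        "test_day",
        "latency_trap_s",
        "latency_head_s",
        "latency_body_s",
        "latency_middle_s",
        "sections_entered",
        "middle_crossings",
        "jumps",
        "activity_scans",
        "activity_prop",
    ],
    "traps": ["trap", "x", "y"],
    "vegetation": ["trap", "x", "y", "max_height_cm", "ground_cover_pct"],
    "metrics": ["individual_id", "site", "sex"],
    "battery": ["response", "score", "estimate", "SE", "chi2", "df", "p"],
}


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    if schema is not None:
        _validate(df, schema)
    df.to_csv(path, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"activity_scans": str} if schema == "tests" else None)
    _validate(df, schema)
    if schema == "tests":
        bad = df["activity_scans"].astype(str).str.len() != 30
        if bad.any():
            raise ValueError(f"{bad.sum()} test records without exactly 30 activity scans")
    return df


def _validate(df: pd.DataFrame, schema: str) -> None:
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required {schema} columns: {missing}")


# ---------------------------------------------------------------------------
# site geometry as GeoJSON


def site_to_geojson(site, path=None) -> dict:
    feats = []
    for i, (x, y) in enumerate(site.trap_locations):
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"kind": "trap", "trap": i},
            }
        )
    geom = site.antenna_geometry
    membership = {
        i: [s for s in SIDES if i in geom.sides[s]] for i in range(8)
    }
    for i, (x, y) in enumerate(geom.antennas):
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"kind": "antenna", "antenna": i, "sides": membership[i]},
            }
        )
    xmin, ymin, xmax, ymax = site.extent
    feats.append(
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax], [xmin, ymin]]
                ],
            },
            "properties": {"kind": "extent"},
        }
    )
    if site.shrub_patches is not None:
        for cx, cy, r in np.atleast_2d(site.shrub_patches):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(cx), float(cy)]},
                    "properties": {"kind": "shrub_patch", "radius_m": float(r)},
                }
            )
    fc = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {"site_id": site.site_id},
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def geometry_from_geojson(source) -> AntennaGeometry:
    """Rebuild the antenna geometry from a site GeoJSON file or mapping."""
    fc = json.loads(Path(source).read_text()) if not isinstance(source, dict) else source
    ants = sorted(
        (f for f in fc["features"] if f["properties"].get("kind") == "antenna"),
        key=lambda f: f["properties"]["antenna"],
    )
    coords = np.array([f["geometry"]["coordinates"] for f in ants])
    sides = {s: tuple(
        f["properties"]["antenna"] for f in ants if s in f["properties"]["sides"]
    ) for s in SIDES}
    return AntennaGeometry(antennas=coords, sides=sides)


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII dialect)


def write_raster(raster: HabitatRaster, path) -> None:
    ny, nx = raster.values.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {raster.x0}\nyllcorner {raster.y0}\n"
        f"cellsize {raster.resolution}\nNODATA_value -9999\n"
    )
    # ESRI ASCII stores the top row first
    body = "\n".join(
        " ".join(f"{v:.6g}" for v in np.nan_to_num(row, nan=-9999.0))
        for row in raster.values[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_raster(path, layer: str = "") -> HabitatRaster:
    lines = Path(path).read_text().splitlines()
    head = {}
    for ln in lines[:6]:
        k, v = ln.split()
        head[k.lower()] = float(v)
    vals = np.loadtxt(lines[6:])
    vals = np.atleast_2d(vals)[::-1]
    vals[vals == head.get("nodata_value", -9999.0)] = np.nan
    return HabitatRaster(
        x0=head["xllcorner"],
        y0=head["yllcorner"],
        resolution=head["cellsize"],
        values=vals,
        layer=layer,
    )


# ---------------------------------------------------------------------------
# configuration


def write_config(config, path) -> None:
    from dataclasses import asdict, is_dataclass

    def plain(obj):
        if is_dataclass(obj):
            return {k: plain(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(plain(config), sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
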