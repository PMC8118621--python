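"""Readers and writers for the pipeline's interchange formats.

Points and admin/habitat polygons travel as GeoJSON (RFC 7946, planar
coordinates in metres); census, events, hierarchy and result tables as CSV
with a header row; the population grid as an ESRI ASCII raster.  Write/read
round-trips preserve values to better than 1e-9; unknown extra columns and
properties are passed through untouched.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .exposure import HABITAT_DEFAULTS, HabitatLayer
from .population import PopulationGrid
from .svi import INDICATORS

logger = logging.getLogger(__name__)


def _jsonify(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_points_geojson(points: pd.DataFrame, path) -> None:
    """Write a shoreline point table as a GeoJSON FeatureCollection."""
    prop_cols = [c for c in points.columns if c not in ("x", "y")]
    features = []
    for row in points.itertuples(index=False):
        d = row._asdict()
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["x"], d["y"]]},
                "properties": {c: _jsonify(d[c]) for c in prop_cols},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_points_geojson(path) -> pd.DataFrame:
    """Read shoreline points written by :func:`write_points_geojson`."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for i, feat in enumerate(gj["features"]):
        geom = feat.get("geometry")
        if not geom or geom.get("type") != "Point":
            raise ValueError(f"feature {i}: expected Point geometry")
        x, y = geom["coordinates"]
        rows.append({"x": x, "y": y, **feat.get("properties", {})})
    df = pd.DataFrame(rows)
    if "point_id" not in df.columns:
        raise ValueError("points GeoJSON missing required property 'point_id'")
    lead = ["point_id", "x", "y"]
    return df[lead + [c for c in df.columns if c not in lead]]


def write_admin_geojson(polygons: dict, path) -> None:
    """Write {unit_id: polygon} as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"unit_id": int(uid)},
        }
        for uid, poly in sorted(polygons.items())
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_admin_geojson(path) -> dict:
    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for i, feat in enumerate(gj["features"]):
        props = feat.get("properties", {})
        if "unit_id" not in props:
            raise ValueError(f"feature {i}: missing required property 'unit_id'")
        try:
            geom = shape(feat["geometry"])
        except Exception as e:  # malformed coordinates etc.
            raise ValueError(f"feature {i}: malformed geometry ({e})") from e
        polys[int(props["unit_id"])] = geom
    return polys


def write_habitats_geojson(layers, path) -> None:
    """Write habitat layers (one feature per polygon, class in properties)."""
    features = []
    for layer in layers:
        for poly in layer.polygons:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {
                        "habitat_class": layer.habitat_class,
                        "protection_rank": layer.protection_rank,
                        "protective_distance_m": layer.protective_distance_m,
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_habitats_geojson(path) -> list:
    """Read habitat layers; classes absent from the file get empty layers."""
    with open(path) as fh:
        gj = json.load(fh)
    by_class = {}
    for i, feat in enumerate(gj["features"]):
        props = feat.get("properties", {})
        for key in ("habitat_class", "protection_rank", "protective_distance_m"):
            if key not in props:
                raise ValueError(f"feature {i}: missing required property '{key}'")
        try:
            geom = shape(feat["geometry"])
        except Exception as e:
            raise ValueError(f"feature {i}: malformed geometry ({e})") from e
        cls = props["habitat_class"]
        layer = by_class.setdefault(
            cls,
            HabitatLayer(
                habitat_class=cls,
                protection_rank=int(props["protection_rank"]),
                protective_distance_m=float(props["protective_distance_m"]),
                polygons=[],
            ),
        )
        layer.polygons.append(geom)
    for cls, defaults in HABITAT_DEFAULTS.items():
        by_class.setdefault(cls, HabitatLayer(habitat_class=cls, polygons=[], **defaults))
    return [by_class[c] for c in sorted(by_class)]


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _read_csv_requiring(path, required, label) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} CSV {path} missing required column(s): {missing}")
    return df


def read_hierarchy_csv(path) -> pd.DataFrame:
    return _read_csv_requiring(path, ["unit_id", "parent_id", "level", "name"], "hierarchy")


def read_census_csv(path) -> pd.DataFrame:
    return _read_csv_requiring(path, ["district_id", *INDICATORS], "census")


def read_events_csv(path) -> pd.DataFrame:
    return _read_csv_requiring(path, ["unit_id", "n_events", "n_fatal_events"], "events")


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII population grid
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: PopulationGrid, path, nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell_size_m!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in grid.counts:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> PopulationGrid:
    """Read an ESRI ASCII grid; NODATA cells become 0 with a logged count."""
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
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
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field '{key}'")
    data = np.loadtxt(lines[i:].__iter__(), dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"ASCII grid {path}: data shape {data.shape} does not match "
            f"header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        n_nodata = int((data == nodata).sum())
        if n_nodata:
            logger.warning("ASCII grid %s: %d NODATA cell(s) treated as 0", path, n_nodata)
            data = np.where(data == nodata, 0.0, data)
    return PopulationGrid(header["xllcorner"], header["yllcorner"], header["cellsize"], data)
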