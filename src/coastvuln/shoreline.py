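"""Sampled-coastline representation and administrative attribution.

The analysis operates on shoreline sample points at fixed spacing (1 km by
default) along a coastline polyline in a projected, planar coordinate system
(metres).  Each point carries the raw biophysical attributes that feed the
exposure ranking and is attributed to exactly one district, which nests in a
province and a country.  Coastline "length" statistics are point counts times
the per-point spacing, so partition conservation (districts -> provinces ->
countries -> region) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from shapely.prepared import prep

#: Columns every shoreline point table carries after sampling.
POINT_GEOM_COLUMNS = ["point_id", "x", "y", "spacing_km"]

#: Raw attribute columns consumed by the exposure engine.
POINT_ATTR_COLUMNS = [
    "relief_m",
    "wave_power",
    "wind_exposure",
    "shelf_distance_m",
    "shoreline_change_rate",
]

ADMIN_LEVELS = ("district", "province", "country", "region")


@dataclass(frozen=True)
class AdminUnit:
    """One node of the district -> province -> country hierarchy."""

    unit_id: int
    level: str
    parent_id: int | None
    name: str


def sample_coastline(polyline, spacing_km: float = 1.0) -> pd.DataFrame:
    """Place sample points along ``polyline`` at fixed arc-length spacing.

    Parameters
    ----------
    polyline : sequence of (x, y) vertices, metres, or shapely LineString
    spacing_km : distance between consecutive points along the line

    Returns
    -------
    DataFrame with columns point_id, x, y, spacing_km.  Points sit at
    arc-length multiples of ``spacing_km`` starting at the first vertex;
    the count is ``floor(length / spacing) + 1``.
    """
    if spacing_km <= 0:
        raise ValueError(f"spacing_km must be > 0, got {spacing_km}")
    line = polyline if isinstance(polyline, LineString) else LineString(polyline)
    length_m = line.length
    if length_m <= 0:
        raise ValueError("degenerate (zero-length) coastline polyline")
    spacing_m = spacing_km * 1000.0
    n = int(np.floor(length_m / spacing_m)) + 1
    dists = np.arange(n) * spacing_m
    pts = [line.interpolate(d) for d in dists]
    return pd.DataFrame(
        {
            "point_id": np.arange(n, dtype=np.int64),
            "x": [p.x for p in pts],
            "y": [p.y for p in pts],
            "spacing_km": float(spacing_km),
        }
    )


def validate_hierarchy(hierarchy: pd.DataFrame) -> None:
    """Check the unit table forms a district -> province -> country tree.

    ``hierarchy`` needs columns unit_id, parent_id, level, name.  Raises
    ``ValueError`` naming the offending unit on broken parent links.
    """
    required = {"unit_id", "parent_id", "level", "name"}
    missing = required - set(hierarchy.columns)
    if missing:
        raise ValueError(f"hierarchy table missing columns: {sorted(missing)}")
    ids = set(hierarchy["unit_id"])
    if len(ids) != len(hierarchy):
        raise ValueError("duplicate unit_id in hierarchy")
    parent_level = {"district": "province", "province": "country"}
    by_id = hierarchy.set_index("unit_id")
    for _, row in hierarchy.iterrows():
        lvl = row["level"]
        if lvl not in ADMIN_LEVELS:
            raise ValueError(f"unit {row['unit_id']}: unknown level {lvl!r}")
        if lvl in parent_level:
            pid = row["parent_id"]
            if pd.isna(pid) or int(pid) not in ids:
                raise ValueError(f"unit {row['unit_id']}: missing parent")
            if by_id.loc[int(pid), "level"] != parent_level[lvl]:
                raise ValueError(
                    f"unit {row['unit_id']}: parent {int(pid)} is not a "
                    f"{parent_level[lvl]}"
                )


def hierarchy_maps(hierarchy: pd.DataFrame) -> tuple[dict, dict]:
    """Return (district -> province, province -> country) id maps."""
    h = hierarchy
    d2p = {
        int(r.unit_id): int(r.parent_id)
        for r in h[h["level"] == "district"].itertuples()
    }
    p2c = {
        int(r.unit_id): int(r.parent_id)
        for r in h[h["level"] == "province"].itertuples()
    }
    return d2p, p2c


def attribute_points(
    points: pd.DataFrame,
    district_polygons: dict,
    hierarchy: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each point its district/province/country by point-in-polygon.

    ``district_polygons`` maps district unit_id -> shapely (Multi)Polygon.
    Boundaries count as inside; a point on a shared boundary goes to the
    polygon with the smaller unit_id (deterministic tie-break).  Points
    covered by no polygon raise ``ValueError`` listing their ids.
    """
    validate_hierarchy(hierarchy)
    d2p, p2c = hierarchy_maps(hierarchy)
    pts = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    district = np.full(len(points), -1, dtype=np.int64)
    # ascending unit_id order implements the tie-break: first cover wins
    for unit_id in sorted(district_polygons):
        poly = prep(district_polygons[unit_id])
        unassigned = district < 0
        if not unassigned.any():
            break
        hits = np.fromiter(
            (poly.covers(p) for p in pts[unassigned]), dtype=bool
        )
        idx = np.flatnonzero(unassigned)[hits]
        district[idx] = unit_id
    if (district < 0).any():
        bad = points["point_id"].to_numpy()[district < 0]
        raise ValueError(
            f"{len(bad)} point(s) fall in no district polygon: "
            f"point_ids {bad[:20].tolist()}"
        )
    out = points.copy()
    out["district_id"] = district
    out["province_id"] = [d2p[d] for d in district]
    out["country_id"] = [p2c[p] for p in out["province_id"]]
    return out


def coastline_length(points: pd.DataFrame, mask=None) -> float:
    """Coastline km represented by the selected points (sum of spacing_km)."""
    if mask is None:
        return float(points["spacing_km"].sum())
    mask = np.asarray(mask, dtype=bool)
    return float(points.loc[mask, "spacing_km"].sum())
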