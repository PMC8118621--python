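"""Coastline sampling, admin attribution and length accounting."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from coastvuln.shoreline import (
    attribute_points,
    coastline_length,
    sample_coastline,
    validate_hierarchy,
)

KM = 1000.0


def arc_interpolate(vertices, dist):
    """Independent cumulative-arc-length point locator."""
    v = np.asarray(vertices, dtype=float)
    seg = np.sqrt(((np.diff(v, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    dist = min(dist, cum[-1])
    i = np.searchsorted(cum, dist, side="right") - 1
    i = min(i, len(seg) - 1)
    t = (dist - cum[i]) / seg[i]
    return v[i] + t * (v[i + 1] - v[i])


def make_hierarchy(district_ids):
    rows = [
        {"unit_id": 900, "parent_id": None, "level": "country", "name": "C"},
        {"unit_id": 910, "parent_id": 900, "level": "province", "name": "P"},
    ]
    rows += [
        {"unit_id": d, "parent_id": 910, "level": "district", "name": f"D{d}"}
        for d in district_ids
    ]
    return pd.DataFrame(rows)


class TestSampleCoastline:
    def test_straight_segment(self):
        pts = sample_coastline([(0, 0), (10 * KM, 0)], spacing_km=1.0)
        assert len(pts) == 11
        np.testing.assert_allclose(pts["x"], np.arange(11) * KM)
        np.testing.assert_allclose(pts["y"], 0.0)

    def test_square_wave_coast(self):
        # total arc length 5.5 km over six segments
        verts = [
            (0, 0), (1 * KM, 0), (1 * KM, 1 * KM), (2 * KM, 1 * KM),
            (2 * KM, 0), (3 * KM, 0), (3 * KM, 0.5 * KM),
        ]
        pts = sample_coastline(verts, spacing_km=1.0)
        assert len(pts) == 6
        for i, row in pts.iterrows():
            expect = arc_interpolate(verts, i * KM)
            np.testing.assert_allclose([row["x"], row["y"]], expect, atol=1e-9)
        # last point at arc length 5.0 km
        np.testing.assert_allclose(
            [pts["x"].iloc[-1], pts["y"].iloc[-1]], arc_interpolate(verts, 5 * KM)
        )

    def test_spacing_exceeds_length(self):
        pts = sample_coastline([(0, 0), (500.0, 0)], spacing_km=1.0)
        assert len(pts) == 1
        assert pts["x"].iloc[0] == 0.0

    def test_degenerate_polyline_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            sample_coastline([(5.0, 5.0), (5.0, 5.0)])

    def test_nonpositive_spacing_errors(self):
        with pytest.raises(ValueError, match="spacing"):
            sample_coastline([(0, 0), (1 * KM, 0)], spacing_km=0)

    def test_invariant_to_vertex_densification(self):
        rng = np.random.default_rng(0)
        verts = np.column_stack(
            [np.arange(12) * KM, rng.normal(0, 300, 12)]
        )
        dense = []
        for a, b in zip(verts[:-1], verts[1:]):
            dense.append(a)
            dense.append((a + b) / 2)
        dense.append(verts[-1])
        p1 = sample_coastline(verts, 1.0)
        p2 = sample_coastline(np.array(dense), 1.0)
        assert len(p1) == len(p2)
        np.testing.assert_allclose(p1[["x", "y"]], p2[["x", "y"]], atol=1e-3)


def ray_cast_inside(poly_xy, x, y):
    """Independent even-odd point-in-polygon oracle (strict interior)."""
    n = len(poly_xy)
    inside = False
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestAttributePoints:
    polys = {
        1: box(0, 0, 1 * KM, 1 * KM),
        2: box(1 * KM, 0, 2 * KM, 1 * KM),
        3: box(2 * KM, 0, 3 * KM, 1 * KM),
    }

    def _points(self, coords):
        return pd.DataFrame(
            {
                "point_id": range(len(coords)),
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
                "spacing_km": 1.0,
            }
        )

    def test_interior_point(self):
        out = attribute_points(
            self._points([(500, 500)]), self.polys, make_hierarchy([1, 2, 3])
        )
        assert out["district_id"].iloc[0] == 1
        assert out["province_id"].iloc[0] == 910
        assert out["country_id"].iloc[0] == 900

    def test_boundary_tie_break_smaller_id(self):
        out = attribute_points(
            self._points([(1 * KM, 500)]), self.polys, make_hierarchy([1, 2, 3])
        )
        assert out["district_id"].iloc[0] == 1

    def test_unassigned_point_errors_with_ids(self):
        with pytest.raises(ValueError, match="point_ids"):
            attribute_points(
                self._points([(500, 500), (9 * KM, 9 * KM)]),
                self.polys,
                make_hierarchy([1, 2, 3]),
            )

    def test_matches_winding_oracle(self):
        rng = np.random.default_rng(1)
        # three irregular convex districts tiling a strip
        polys_xy = {
            5: [(0, 0), (1.2 * KM, 0), (1.0 * KM, 1 * KM), (0, 1 * KM)],
            6: [(1.2 * KM, 0), (2.1 * KM, 0), (2.3 * KM, 1 * KM), (1.0 * KM, 1 * KM)],
            7: [(2.1 * KM, 0), (3.5 * KM, 0), (3.5 * KM, 1 * KM), (2.3 * KM, 1 * KM)],
        }
        from shapely.geometry import Polygon

        polys = {k: Polygon(v) for k, v in polys_xy.items()}
        xs = rng.uniform(50, 3450, 200)
        ys = rng.uniform(50, 950, 200)
        out = attribute_points(self._points(list(zip(xs, ys))), polys, make_hierarchy([5, 6, 7]))
        for _, row in out.iterrows():
            oracle = [k for k, v in polys_xy.items() if ray_cast_inside(v, row["x"], row["y"])]
            if len(oracle) == 1:  # strict-interior points only
                assert row["district_id"] == oracle[0]


class TestCoastlineLength:
    def test_predicate_sum(self):
        pts = pd.DataFrame({"point_id": range(10), "spacing_km": 1.0})
        mask = np.zeros(10, dtype=bool)
        mask[:2] = True
        assert coastline_length(pts, mask) == 2.0

    def test_empty_subset(self):
        pts = pd.DataFrame({"point_id": range(10), "spacing_km": 1.0})
        assert coastline_length(pts, np.zeros(10, dtype=bool)) == 0.0

    def test_partition_conservation(self, region):
        pts = region["points"]
        total = coastline_length(pts)
        by_d = pts.groupby("district_id")["spacing_km"].sum().sum()
        by_p = pts.groupby("province_id")["spacing_km"].sum().sum()
        by_c = pts.groupby("country_id")["spacing_km"].sum().sum()
        assert total == by_d == by_p == by_c


def test_validate_hierarchy_rejects_orphan():
    h = make_hierarchy([1])
    h.loc[h["unit_id"] == 1, "parent_id"] = 999
    with pytest.raises(ValueError, match="parent"):
        validate_hierarchy(h)
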