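"""Seeded synthetic coastal regions for end-to-end runs and testing.

Real applications of this pipeline draw on global datasets (DEM relief, wave
hindcasts, habitat atlases, gridded population, national censuses, disaster
inventories).  This module emulates their statistical structure so every
stage can run and be validated without downloads: a smooth random coastline
sampled at fixed spacing; positive, spatially autocorrelated biophysical
fields (moving-average-smoothed noise); shoreline-change rates present only
on contiguous "sandy" stretches; habitat polygons as along-coast ribbons with
prescribed coverage fractions; population clustered near the coast;
correlated lognormal census indicators; and per-district hazard-event counts
whose log-rate increases with the district's true share of higher-exposure
coastline.

Everything is a deterministic function of ``RegionSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, box
from shapely.ops import substring

from . import exposure as ex
from .population import PopulationGrid
from .shoreline import attribute_points, sample_coastline
from .svi import INDICATORS

#: Lognormal (median, log-sd) per census indicator; medians follow the
#: regional averages the assessment context reports for housing/sanitation
#: and typical East African demographic rates elsewhere.
CENSUS_MODEL = {
    "pct_under4": (15.0, 0.25),
    "pct_over65": (4.0, 0.30),
    "pct_annual_growth": (2.5, 0.30),
    "density_per_km2": (100.0, 0.90),
    "pct_illiterate": (30.0, 0.50),
    "pct_natural_housing": (60.0, 0.35),
    "pct_unimproved_water": (40.0, 0.50),
    "pct_unimproved_waste": (55.0, 0.40),
}


@dataclass
class RegionSpec:
    """Parameters of one synthetic coastal region.

    Habitat coverage defaults reflect the regional shares of coastline
    protected by each habitat class in the East African assessment context
    (mangrove ~60%, coral reef ~34%, seagrass ~8%); the event model's
    log-rate is baseline + slope * (fraction of points at higher
    exposure).
    """

    seed: int = 0
    n_countries: int = 2
    provinces_per_country: int = 2
    districts_per_province: int = 3
    coast_length_km: float = 600.0
    point_spacing_km: float = 1.0
    field_correlation_km: float = 25.0
    coast_amplitude_km: float = 3.0
    habitat_cover: dict = field(
        default_factory=lambda: {"mangrove": 0.60, "coral_reef": 0.34, "seagrass": 0.08}
    )
    protective_distances_m: dict = field(
        default_factory=lambda: {
            k: v["protective_distance_m"] for k, v in ex.HABITAT_DEFAULTS.items()
        }
    )
    sandy_fraction: float = 0.5
    sandy_cycle_km: float = 30.0
    population_total: float = 2_000_000.0
    pop_decay_km: float = 5.0
    grid_cell_km: float = 1.0
    grid_margin_km: float = 10.0
    census_correlation: float = 0.5
    baseline_log_rate: float = 0.5
    exposure_slope: float = 2.0
    fatal_fraction: float = 0.4

    @property
    def n_districts(self) -> int:
        return self.n_countries * self.provinces_per_country * self.districts_per_province


def _smooth_series(rng, n: int, corr_steps: float) -> np.ndarray:
    """Moving-average-smoothed standard noise with unit variance."""
    w = max(int(round(corr_steps)), 1)
    raw = rng.standard_normal(n + 2 * w)
    kernel = np.ones(w) / w
    sm = np.convolve(raw, kernel, mode="same")[w:-w]
    sd = sm.std()
    return (sm - sm.mean()) / sd if sd > 0 else np.zeros(n)


def _sandy_mask(rng, n: int, spacing_km: float, frac: float, cycle_km: float) -> np.ndarray:
    """Contiguous sandy/rocky runs with the target sandy fraction."""
    if frac <= 0:
        return np.zeros(n, dtype=bool)
    if frac >= 1:
        return np.ones(n, dtype=bool)
    mean_sandy = max(frac * cycle_km / spacing_km, 1.0)
    mean_rocky = max((1 - frac) * cycle_km / spacing_km, 1.0)
    mask = np.zeros(n, dtype=bool)
    pos = 0
    sandy = rng.random() < frac
    while pos < n:
        mean = mean_sandy if sandy else mean_rocky
        run = max(int(np.ceil(rng.exponential(mean))), 1)
        if sandy:
            mask[pos : pos + run] = True
        pos += run
        sandy = not sandy
    return mask


def _habitat_patches(rng, line: LineString, frac: float, reach_m: float) -> list:
    """Along-coast ribbon polygons covering ~frac of the arc length."""
    if frac <= 0:
        return []
    total_m = line.length
    nominal_m = 40_000.0
    n_patches = max(int(round(frac * total_m / nominal_m)), 1)
    block = total_m / n_patches
    # each patch effectively covers its length plus the reach on both ends
    patch_len = np.clip(frac * block - 2 * reach_m, 2_000.0, block * 0.95)
    polys = []
    for i in range(n_patches):
        lo = i * block
        start = lo + rng.uniform(0, max(block - patch_len, 1.0))
        seg = substring(line, start, min(start + patch_len, total_m))
        polys.append(seg.buffer(300.0))
    return polys


def simulate_event_table(
    rng,
    pct_higher,
    baseline_log_rate: float = 0.5,
    exposure_slope: float = 2.0,
    fatal_fraction: float = 0.4,
) -> pd.DataFrame:
    """Hazard-event counts per unit under the Poisson log-rate model.

    n_events ~ Poisson(exp(baseline + slope * pct_higher/100)); each event
    independently causes fatalities with probability ``fatal_fraction``,
    so n_fatal_events <= n_events always.
    """
    pct = np.asarray(pct_higher, dtype=float)
    rate = np.exp(baseline_log_rate + exposure_slope * pct / 100.0)
    n_events = rng.poisson(rate)
    n_fatal = rng.binomial(n_events, fatal_fraction)
    return pd.DataFrame(
        {"n_events": n_events.astype(np.int64), "n_fatal_events": n_fatal.astype(np.int64)}
    )


def generate_region(spec: RegionSpec) -> dict:
    """Generate one complete synthetic region.

    Returns a dict with keys: points (attributed shoreline table),
    hierarchy, admin_polygons (district id -> polygon), habitat_layers,
    population_grid, census, events.
    """
    if spec.point_spacing_km > spec.coast_length_km:
        raise ValueError("point spacing exceeds coastline length")
    if spec.coast_length_km / spec.point_spacing_km < spec.n_districts:
        raise ValueError("fewer shoreline points than districts")
    rng = np.random.default_rng(spec.seed)

    # --- coastline: x advances monotonically, y wanders smoothly ---------
    vstep_km = 0.25
    nv = int(spec.coast_length_km / vstep_km) + 1
    xs = np.arange(nv) * vstep_km * 1000.0
    ys = _smooth_series(rng, nv, spec.field_correlation_km / vstep_km)
    ys = ys * spec.coast_amplitude_km * 1000.0
    line = LineString(np.column_stack([xs, ys]))
    points = sample_coastline(line, spec.point_spacing_km)
    n = len(points)

    # --- admin hierarchy and district slab polygons ----------------------
    hierarchy_rows = [{"unit_id": 0, "parent_id": None, "level": "region", "name": "Region"}]
    district_ids = []
    for c in range(spec.n_countries):
        cid = 1 + c
        hierarchy_rows.append(
            {"unit_id": cid, "parent_id": 0, "level": "country", "name": f"Country {c + 1}"}
        )
        for p in range(spec.provinces_per_country):
            pid = 100 + c * spec.provinces_per_country + p
            hierarchy_rows.append(
                {"unit_id": pid, "parent_id": cid, "level": "province", "name": f"Province {pid - 99}"}
            )
            for d in range(spec.districts_per_province):
                did = 1000 + len(district_ids)
                district_ids.append(did)
                hierarchy_rows.append(
                    {"unit_id": did, "parent_id": pid, "level": "district", "name": f"District {did - 999}"}
                )
    hierarchy = pd.DataFrame(hierarchy_rows)

    blocks = np.array_split(np.arange(n), spec.n_districts)
    pad = 50_000.0
    ymin, ymax = points["y"].min() - pad, points["y"].max() + pad
    cuts = [points["x"].min() - pad]
    for left, right in zip(blocks[:-1], blocks[1:]):
        cuts.append(0.5 * (points["x"].iloc[left[-1]] + points["x"].iloc[right[0]]))
    cuts.append(points["x"].max() + pad)
    admin_polygons = {
        did: box(cuts[i], ymin, cuts[i + 1], ymax) for i, did in enumerate(district_ids)
    }

    # --- biophysical fields ----------------------------------------------
    corr = spec.field_correlation_km / spec.point_spacing_km
    points["relief_m"] = np.exp(1.2 + 1.0 * _smooth_series(rng, n, corr))
    points["wave_power"] = np.minimum(np.exp(2.0 + 1.5 * _smooth_series(rng, n, corr)), 219.77)
    points["wind_exposure"] = np.exp(3.0 + 0.8 * _smooth_series(rng, n, corr))
    points["shelf_distance_m"] = np.exp(9.0 + 1.0 * _smooth_series(rng, n, corr))
    rates = 2.0 * _smooth_series(rng, n, corr) + 0.3 * rng.standard_normal(n)
    sandy = _sandy_mask(rng, n, spec.point_spacing_km, spec.sandy_fraction, spec.sandy_cycle_km)
    points["shoreline_change_rate"] = np.where(sandy, rates, np.nan)

    points = attribute_points(points, admin_polygons, hierarchy)

    # --- habitat ribbons ---------------------------------------------------
    habitat_layers = []
    for cls, defaults in ex.HABITAT_DEFAULTS.items():
        reach = spec.protective_distances_m.get(cls, defaults["protective_distance_m"])
        polys = _habitat_patches(rng, line, spec.habitat_cover.get(cls, 0.0), reach)
        habitat_layers.append(
            ex.HabitatLayer(
                habitat_class=cls,
                protection_rank=defaults["protection_rank"],
                protective_distance_m=reach,
                polygons=polys,
            )
        )

    # --- population grid (coast-clustered) -------------------------------
    m = spec.grid_margin_km * 1000.0
    cs = spec.grid_cell_km * 1000.0
    xll = float(points["x"].min() - m)
    yll = float(points["y"].min() - m)
    ncols = int(np.ceil((points["x"].max() + m - xll) / cs))
    nrows = int(np.ceil((points["y"].max() + m - yll) / cs))
    grid = PopulationGrid(xll, yll, cs, np.zeros((nrows, ncols)))
    centers = grid.cell_centers()
    d, _ = cKDTree(points[["x", "y"]].to_numpy()).query(centers, k=1)
    w = np.exp(-d / (spec.pop_decay_km * 1000.0)) * np.exp(0.5 * rng.standard_normal(len(centers)))
    counts = spec.population_total * w / w.sum()
    grid.counts = counts.reshape(nrows, ncols)

    # --- census indicators (correlated lognormal per district) -----------
    nd = spec.n_districts
    common = rng.standard_normal(nd)
    rho = spec.census_correlation
    census = pd.DataFrame({"district_id": district_ids})
    for name in INDICATORS:
        median, sigma = CENSUS_MODEL[name]
        z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(nd)
        vals = median * np.exp(sigma * z)
        if name.startswith("pct_"):
            vals = np.clip(vals, 0.0, 100.0)
        census[name] = vals
    # --- hazard events driven by the true exposure (scenario 1) ----------
    exp_s1 = ex.run_scenarios(points, habitat_layers, scenarios=["S1_all"])
    merged = points[["point_id", "district_id"]].merge(exp_s1, on="point_id")
    pct_h = (
        merged.groupby("district_id")["lmh"]
        .apply(lambda s: 100.0 * (s == "H").mean())
        .reindex(district_ids)
        .to_numpy()
    )
    events = simulate_event_table(
        rng, pct_h, spec.baseline_log_rate, spec.exposure_slope, spec.fatal_fraction
    )
    events.insert(0, "unit_id", district_ids)

    return {
        "points": points,
        "hierarchy": hierarchy,
        "admin_polygons": admin_polygons,
        "habitat_layers": habitat_layers,
        "population_grid": grid,
        "census": census,
        "events": events,
    }


# --------------------------------------------------------------------------
# Worked-example fixture from the published regional summary table
# --------------------------------------------------------------------------

#: (name, level, parent, n_points, H in S1, H in S5, pop S1, pop S5) —
#: coastline totals and higher-exposure lengths (1 point = 1 km) and
#: population at higher exposure (thousands) as printed in the source
#: regional summary; "rest of X" rows are the country remainders after
#: subtracting the named most-exposed province.
_REGIONAL_SUMMARY = [
    ("East Africa", "region", None, 22112, 4827, 8603, 3536.8, 6898.8),
    ("Kenya", "country", "East Africa", 1591, 228, 581, 314.6, 1298.5),
    ("Tana River", "province", "Kenya", 99, 64, 76, 15.2, 15.6),
    ("Rest of Kenya", "province", "Kenya", 1492, 164, 505, None, None),
    ("Tanzania", "country", "East Africa", 3138, 309, 1039, 405.1, 2204.7),
    ("Pwani", "province", "Tanzania", 636, 159, 339, 53.6, 80.8),
    ("Rest of Tanzania", "province", "Tanzania", 2502, 150, 700, None, None),
    ("Mozambique", "country", "East Africa", 7146, 1670, 2500, 1660.4, 1899.9),
    ("Gaza", "province", "Mozambique", 202, 154, 154, 76.3, 76.3),
    ("Rest of Mozambique", "province", "Mozambique", 6944, 1516, 2346, None, None),
    ("Madagascar", "country", "East Africa", 10237, 2620, 4483, 1156.8, 1495.7),
    ("Androy", "province", "Madagascar", 211, 172, 187, 71.8, 72.1),
    ("Rest of Madagascar", "province", "Madagascar", 10026, 2448, 4296, None, None),
]


def regional_summary_fixture() -> dict:
    """Point-level fixture reproducing the published regional summary.

    Expands the printed per-unit coastline totals and higher-exposure
    counts into shoreline points (1-km spacing, one district per province
    row) and matching per-point exposure results for scenarios S1 (all
    habitats) and S5 (no habitats), so the summarization/reporting path
    can recompute the printed percentages.  H point sets are nested
    (S1 subset of S5).  Returns dict with keys units, points, exposure,
    hierarchy.
    """
    units = pd.DataFrame(
        _REGIONAL_SUMMARY,
        columns=["name", "level", "parent", "n_points", "h_s1", "h_s5", "pop_s1_thousands", "pop_s5_thousands"],
    )
    name_to_id = {}
    hierarchy_rows = []
    next_ids = {"region": 0, "country": 1, "province": 100}
    for r in units.itertuples():
        uid = next_ids[r.level]
        next_ids[r.level] += 1
        name_to_id[r.name] = uid
        hierarchy_rows.append(
            {
                "unit_id": uid,
                "parent_id": None if r.parent is None else name_to_id[r.parent],
                "level": r.level,
                "name": r.name,
            }
        )
    # one district per province, mirroring the province extents
    prov_rows = [h for h in hierarchy_rows if h["level"] == "province"]
    for i, h in enumerate(prov_rows):
        hierarchy_rows.append(
            {"unit_id": 1000 + i, "parent_id": h["unit_id"], "level": "district", "name": f"D-{h['name']}"}
        )
    hierarchy = pd.DataFrame(hierarchy_rows)
    units["unit_id"] = [name_to_id[n] for n in units["name"]]

    pt_rows = []
    exp_rows = []
    pid_counter = 0
    for i, r in enumerate(units[units["level"] == "province"].itertuples()):
        did = 1000 + i
        country_id = [h["parent_id"] for h in hierarchy_rows if h["unit_id"] == r.unit_id][0]
        for j in range(r.n_points):
            pt_rows.append(
                {
                    "point_id": pid_counter,
                    "x": 1000.0 * pid_counter,
                    "y": 0.0,
                    "spacing_km": 1.0,
                    "district_id": did,
                    "province_id": r.unit_id,
                    "country_id": country_id,
                }
            )
            for scen, h_count in (("S1_all", r.h_s1), ("S5_no_habitats", r.h_s5)):
                is_h = j < h_count
                exp_rows.append(
                    {
                        "point_id": pid_counter,
                        "scenario": scen,
                        "ie": 4.2 if is_h else 2.0,
                        "ie_class": 4 if is_h else 2,
                        "lmh": "H" if is_h else "L",
                    }
                )
            pid_counter += 1
    return {
        "units": units,
        "points": pd.DataFrame(pt_rows),
        "exposure": pd.DataFrame(exp_rows),
        "hierarchy": hierarchy,
    }
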