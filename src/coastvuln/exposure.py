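"""Exposure ranking and the geometric-mean index of exposure (IE).

Six biophysical variables are each ranked 1 (very low exposure) to 5 (very
high): relief, wave exposure, wind exposure, surge potential (distance to the
30-m depth contour), natural-habitat protection, and shoreline change rate.
Relief, waves and shoreline change use fixed class boundaries; wind and surge
are ranked by region-wide quintiles.  The IE of a shoreline point is the
geometric mean of its six ranks,

    IE = (R_relief * R_waves * R_wind * R_surge * R_habitats * R_change)^(1/6)

and is collapsed to lower / moderate / higher (L/M/H) classes for reporting.
Habitat-loss scenarios re-rank only the habitat variable, holding the other
five fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

RANKS = (1, 2, 3, 4, 5)

RANK_COLUMNS = [
    "r_relief",
    "r_waves",
    "r_wind",
    "r_surge",
    "r_habitats",
    "r_shoreline_change",
]


@dataclass(frozen=True)
class RankingScheme:
    """Rank-assignment rule for one variable.

    For ``method="fixed_bins"``, ``edges`` are the four interior class
    boundaries in ascending raw-value order; intervals are closed at the
    lower edge, open at the upper, and out-of-range values clamp to the
    extreme class on that side.  ``ascending=True`` means larger raw values
    rank as higher exposure (rank increases with value); ``ascending=False``
    reverses the direction (e.g. low-lying relief is the most exposed).
    """

    variable: str
    method: str = "fixed_bins"  # or "quantile"
    edges: tuple = ()
    ascending: bool = True

    def __post_init__(self):
        if self.method == "fixed_bins":
            if len(self.edges) != 4:
                raise ValueError(
                    f"{self.variable}: fixed_bins needs exactly 4 interior "
                    f"edges, got {len(self.edges)}"
                )
            if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError(f"{self.variable}: edges must strictly ascend")
        elif self.method != "quantile":
            raise ValueError(f"unknown ranking method {self.method!r}")


# Default class boundaries.  The wave row's published limits leave a small
# gap between 18.70 and 18.75; the contiguous edges below close it so every
# value receives a rank.
DEFAULT_SCHEMES = {
    "relief": RankingScheme("relief", "fixed_bins", (2.0, 4.0, 8.0, 12.0), ascending=False),
    "wave": RankingScheme("wave", "fixed_bins", (0.75, 3.0, 18.75, 48.0), ascending=True),
    "wind": RankingScheme("wind", "quantile"),
    "surge": RankingScheme("surge", "quantile"),
}


@dataclass
class HabitatLayer:
    """Polygons of one habitat class with its protection rank and reach.

    Coral reefs and mangroves carry protection rank 1 (strongest reduction
    of exposure), seagrass rank 4; shoreline with no habitat within reach
    ranks 5.  ``protective_distance_m`` is the radius within which the
    habitat confers its rank on a shoreline point.
    """

    habitat_class: str
    protection_rank: int
    protective_distance_m: float
    polygons: list = field(default_factory=list)

    def __post_init__(self):
        if self.protection_rank not in (1, 4):
            raise ValueError(
                f"protection_rank must be 1 or 4, got {self.protection_rank}"
            )
        if self.protective_distance_m <= 0:
            raise ValueError("protective_distance_m must be > 0")


#: Default protection ranks and protective radii per habitat class.  The
#: radii are working assumptions (configurable), not published values.
HABITAT_DEFAULTS = {
    "coral_reef": {"protection_rank": 1, "protective_distance_m": 2000.0},
    "mangrove": {"protection_rank": 1, "protective_distance_m": 1000.0},
    "seagrass": {"protection_rank": 4, "protective_distance_m": 500.0},
}

NO_HABITAT_RANK = 5

#: The five habitat-presence scenarios.  S1 is "current conditions"; S2-S4
#: each remove one habitat class; S5 removes all (R_habitats = 5 everywhere).
SCENARIOS = {
    "S1_all": frozenset({"coral_reef", "mangrove", "seagrass"}),
    "S2_no_corals": frozenset({"mangrove", "seagrass"}),
    "S3_no_mangrove": frozenset({"coral_reef", "seagrass"}),
    "S4_no_seagrasses": frozenset({"coral_reef", "mangrove"}),
    "S5_no_habitats": frozenset(),
}

SCENARIO_ORDER = list(SCENARIOS)


def rank_fixed_bins(values, scheme: RankingScheme):
    """Rank value(s) into the five fixed classes of ``scheme``.

    Lower-closed / upper-open intervals; values beyond the outermost
    published limits clamp to the extreme class on that side.
    """
    if scheme.method != "fixed_bins":
        raise ValueError(f"{scheme.variable} is not a fixed_bins scheme")
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{scheme.variable}: non-finite value in input")
    idx = np.searchsorted(np.asarray(scheme.edges), arr, side="right")
    ranks = idx + 1 if scheme.ascending else 5 - idx
    return ranks if arr.ndim else int(ranks)


def rank_quantile(values) -> np.ndarray:
    """Rank values 1-5 by region-wide quintiles.

    Breakpoints are the 20/40/60/80th percentiles (linear interpolation).
    A value equal to a breakpoint goes to the lower class; a constant
    vector therefore collapses to all rank 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError(f"quantile ranking needs >= 5 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError("quantile ranking: non-finite value in input")
    breaks = np.percentile(arr, [20, 40, 60, 80])
    return np.searchsorted(breaks, arr, side="left").astype(np.int64) + 1


def shoreline_change_rank(rates, missing_rank: int = 3):
    """Rank shoreline change rates (m/yr): accretion 1 ... erosion 5.

    > +2 -> 1; (+1, +2] -> 2; [-1, +1] -> 3; [-2, -1) -> 4; < -2 -> 5.
    Rates are only observed on sandy shores; missing values (NaN) take
    ``missing_rank`` (neutral 3 by default).
    """
    arr = np.atleast_1d(np.asarray(rates, dtype=float))
    ranks = np.full(arr.shape, missing_rank, dtype=np.int64)
    obs = np.isfinite(arr)
    v = arr[obs]
    r = np.empty(v.shape, dtype=np.int64)
    r[v > 2] = 1
    r[(v > 1) & (v <= 2)] = 2
    r[(v >= -1) & (v <= 1)] = 3
    r[(v >= -2) & (v < -1)] = 4
    r[v < -2] = 5
    ranks[obs] = r
    return ranks if np.ndim(rates) else int(ranks[0])


def habitat_rank(points_xy, habitat_layers, scenario: str):
    """Habitat-protection rank per point under a scenario.

    Among the habitat classes present in the scenario that have a polygon
    within their protective distance of the point, the minimum protection
    rank applies (the most protective habitat wins); with none in reach the
    rank is 5.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    included = SCENARIOS[scenario]
    xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    pts = shapely.points(xy[:, 0], xy[:, 1])
    ranks = np.full(len(pts), NO_HABITAT_RANK, dtype=np.int64)
    for layer in habitat_layers:
        if layer.habitat_class not in included or not layer.polygons:
            continue
        geom = unary_union(layer.polygons)
        d = shapely.distance(pts, geom)
        ranks = np.where(
            d <= layer.protective_distance_m,
            np.minimum(ranks, layer.protection_rank),
            ranks,
        )
    return ranks if np.ndim(points_xy) == 2 else int(ranks[0])


def compute_ie(ranks):
    """Geometric mean of the six variable ranks.

    ``ranks`` is a length-6 sequence or an (n, 6) array of integers 1-5.
    """
    arr = np.asarray(ranks, dtype=float)
    if arr.shape[-1] != 6:
        raise ValueError(f"expected six ranks, got shape {arr.shape}")
    if ((arr < 1) | (arr > 5)).any() or (arr != np.round(arr)).any():
        raise ValueError("ranks must be integers in 1..5")
    ie = np.exp(np.log(arr).mean(axis=-1))
    return ie if arr.ndim > 1 else float(ie)


def classify_ie(ie_values, rule: str = "round"):
    """Collapse continuous IE to the 1-5 class and the L/M/H label.

    Default rule ("round"): nearest integer with halves rounding up, so a
    point is "higher exposure" (H, classes 4-5) iff IE >= 3.5.  L combines
    classes 1-2, M is class 3.  ``rule="quantile"`` instead assigns the
    class by region-wide quintiles of the IE values.
    """
    arr = np.atleast_1d(np.asarray(ie_values, dtype=float))
    if ((arr < 1) | (arr > 5)).any():
        raise ValueError("IE values must lie in [1, 5]")
    if rule == "round":
        cls = np.floor(arr + 0.5).astype(np.int64)
        np.clip(cls, 1, 5, out=cls)
    elif rule == "quantile":
        cls = rank_quantile(arr)
    else:
        raise ValueError(f"unknown IE classing rule {rule!r}")
    lmh = np.where(cls <= 2, "L", np.where(cls == 3, "M", "H"))
    if np.ndim(ie_values):
        return cls, lmh
    return int(cls[0]), str(lmh[0])


def rank_variables(points: pd.DataFrame, schemes=None, missing_change_rank: int = 3) -> pd.DataFrame:
    """Rank the five non-habitat variables for every shoreline point.

    Wind and surge quintile breakpoints are taken over the whole input
    table in one pass (the comparison is region-wide, not per country).
    """
    schemes = {**DEFAULT_SCHEMES, **(schemes or {})}
    return pd.DataFrame(
        {
            "point_id": points["point_id"].to_numpy(),
            "r_relief": rank_fixed_bins(points["relief_m"].to_numpy(), schemes["relief"]),
            "r_waves": rank_fixed_bins(points["wave_power"].to_numpy(), schemes["wave"]),
            "r_wind": rank_quantile(points["wind_exposure"].to_numpy()),
            "r_surge": rank_quantile(points["shelf_distance_m"].to_numpy()),
            "r_shoreline_change": shoreline_change_rank(
                points["shoreline_change_rate"].to_numpy(), missing_change_rank
            ),
        }
    )


def run_scenarios(
    points: pd.DataFrame,
    habitat_layers,
    scenarios=None,
    schemes=None,
    missing_change_rank: int = 3,
    ie_classing: str = "round",
) -> pd.DataFrame:
    """Compute per-point exposure for each habitat scenario.

    The five non-habitat ranks are computed once and shared; only the
    habitat rank (and hence IE) varies across scenarios.  Returns a long
    table with one row per point per scenario: the six ranks, ie,
    ie_class and lmh.
    """
    scenarios = list(SCENARIOS) if scenarios is None else list(scenarios)
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")
    base = rank_variables(points, schemes, missing_change_rank)
    xy = points[["x", "y"]].to_numpy()
    frames = []
    for scen in scenarios:
        df = base.copy()
        df.insert(1, "scenario", scen)
        df["r_habitats"] = habitat_rank(xy, habitat_layers, scen)
        ranks = df[RANK_COLUMNS].to_numpy()
        df["ie"] = compute_ie(ranks)
        cls, lmh = classify_ie(df["ie"].to_numpy(), ie_classing)
        df["ie_class"] = cls
        df["lmh"] = lmh
        frames.append(df[["point_id", "scenario", *RANK_COLUMNS, "ie", "ie_class", "lmh"]])
    return pd.concat(frames, ignore_index=True)
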