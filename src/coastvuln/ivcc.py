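"""Admin-level summaries, the IVCC, and priority classification.

Per administrative unit the exposure results collapse to a mean IE and the
percentage of shoreline points at higher exposure.  The index of
vulnerability to coastal change (IVCC) is the sum of the unit's social
vulnerability rank (district SVI, or mean district SVI at province level)
and its mean IE, so it ranges over [2, 10].  Districts with IVCC > 7 are
areas of priority concern; those additionally showing > 90% of their
coastline at higher exposure under current conditions (scenario 1) are
critical areas.  Units without census data carry no SVI and hence no IVCC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ID_COL = {
    "district": "district_id",
    "province": "province_id",
    "country": "country_id",
}


def summarize_admin(
    exposure: pd.DataFrame,
    points: pd.DataFrame,
    level: str = "district",
    scenario: str = "S1_all",
) -> pd.DataFrame:
    """Mean IE, % of points at H, and coastline km per unit at ``level``.

    ``level="region"`` pools every point into a single row (unit_id 0).
    mean_ie averages point IE values directly (not district means), so
    provinces weight districts by their point counts.
    """
    exp = exposure[exposure["scenario"] == scenario]
    if level == "region":
        pts = points.copy()
        pts["_unit"] = 0
    else:
        if level not in _ID_COL:
            raise ValueError(f"unknown admin level {level!r}")
        pts = points.copy()
        pts["_unit"] = pts[_ID_COL[level]]
    merged = pts.merge(exp, on="point_id", how="inner")
    if len(merged) < len(pts):
        logger.warning(
            "%d point(s) lack exposure results for %s and are dropped",
            len(pts) - len(merged), scenario,
        )
    rows = []
    for unit_id, grp in merged.groupby("_unit"):
        n = len(grp)
        n_h = int((grp["lmh"] == "H").sum())
        rows.append(
            {
                "unit_id": unit_id,
                "level": level,
                "scenario": scenario,
                "n_points": n,
                "n_higher": n_h,
                "coast_km": float(grp["spacing_km"].sum()),
                "coast_km_higher": float(grp.loc[grp["lmh"] == "H", "spacing_km"].sum()),
                "mean_ie": float(grp["ie"].mean()),
                "pct_higher": 100.0 * n_h / n,
            }
        )
    return pd.DataFrame(rows)


def compute_ivcc(svi_value: float, mean_ie: float) -> float:
    """IVCC = SVI + mean IE (each in [1, 5], so IVCC in [2, 10])."""
    if not 1.0 <= svi_value <= 5.0:
        raise ValueError(f"SVI must lie in [1, 5], got {svi_value}")
    if not 1.0 <= mean_ie <= 5.0:
        raise ValueError(f"mean IE must lie in [1, 5], got {mean_ie}")
    return float(svi_value) + float(mean_ie)


def classify_priority(ivcc, pct_higher_s1) -> str:
    """Priority classification from IVCC and % coastline at H (scenario 1).

    'priority_concern' iff IVCC > 7 (strict); 'critical' additionally
    requires pct_higher_s1 > 90 (strict); otherwise 'none'.  Units lacking
    an IVCC (no SVI) classify as 'none'.
    """
    if ivcc is None or (isinstance(ivcc, float) and np.isnan(ivcc)):
        return "none"
    if not 2.0 <= ivcc <= 10.0:
        raise ValueError(f"IVCC must lie in [2, 10], got {ivcc}")
    if not 0.0 <= pct_higher_s1 <= 100.0:
        raise ValueError(f"pct_higher must lie in [0, 100], got {pct_higher_s1}")
    if ivcc > 7.0:
        return "critical" if pct_higher_s1 > 90.0 else "priority_concern"
    return "none"


def build_admin_summary(
    exposure: pd.DataFrame,
    points: pd.DataFrame,
    svi_by_unit: pd.Series | None = None,
    level: str = "district",
    scenarios=None,
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Wide per-unit table across scenarios with SVI, IVCC and priority class.

    ``svi_by_unit`` maps unit_id -> SVI value at this level (district rank
    or province mean rank); units absent from it get no SVI/IVCC and a
    'none' priority class.  ``population`` is an optional long table from
    :func:`coastvuln.population.population_by_admin` covering the same
    scenarios.
    """
    scenarios = list(dict.fromkeys(exposure["scenario"])) if scenarios is None else list(scenarios)
    base = None
    for scen in scenarios:
        s = summarize_admin(exposure, points, level, scen).set_index("unit_id")
        cols = {
            f"mean_ie_{scen}": s["mean_ie"],
            f"pct_higher_{scen}": s["pct_higher"],
            f"coast_km_higher_{scen}": s["coast_km_higher"],
        }
        if base is None:
            base = pd.DataFrame(
                {"n_points": s["n_points"], "coast_km": s["coast_km"]}
            )
        base = base.assign(**cols)
    if population is not None:
        for scen in scenarios:
            p = population[population["scenario"] == scen].set_index("unit_id")
            base[f"population_higher_{scen}"] = p["population_higher"].reindex(base.index)
    if svi_by_unit is not None:
        base["svi"] = pd.Series(svi_by_unit).reindex(base.index)
        for scen in scenarios:
            base[f"ivcc_{scen}"] = base["svi"] + base[f"mean_ie_{scen}"]
    else:
        base["svi"] = np.nan
        for scen in scenarios:
            base[f"ivcc_{scen}"] = np.nan
    ref = "S1_all" if "S1_all" in scenarios else scenarios[0]
    base["priority"] = [
        classify_priority(
            None if pd.isna(row[f"ivcc_{ref}"]) else float(row[f"ivcc_{ref}"]),
            float(row[f"pct_higher_{ref}"]),
        )
        for _, row in base.iterrows()
    ]
    base.index.name = "unit_id"
    base.insert(0, "level", level)
    return base.reset_index()
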