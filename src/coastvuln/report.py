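"""Regional summary reporting.

Builds the headline table of the assessment: per region, country and
province — total coastline km, km and % at higher exposure under each
habitat scenario, and (when a population grid is supplied) people within the
buffer of higher-exposure coastline.  Percentages and mean indices are
reported to one decimal (half-up), matching the conventions of published
summary tables; underlying CSVs keep full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ivcc import summarize_admin


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 100*2620/10237 -> 25.6, 34.95 -> 35.0)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def region_report(
    exposure: pd.DataFrame,
    points: pd.DataFrame,
    hierarchy: pd.DataFrame,
    scenarios=("S1_all", "S5_no_habitats"),
    population: dict | None = None,
    levels=("region", "country", "province"),
) -> pd.DataFrame:
    """Summary table across administrative levels for the given scenarios.

    ``population`` optionally maps scenario -> {level -> DataFrame from
    population_by_admin}.  Output columns: unit_id, level, name, coast_km,
    then per scenario km/% at higher exposure (one-decimal %) and
    population at higher exposure.
    """
    names = hierarchy.set_index("unit_id")["name"].to_dict()
    frames = []
    for level in levels:
        base = None
        for scen in scenarios:
            s = summarize_admin(exposure, points, level, scen).set_index("unit_id")
            if base is None:
                base = pd.DataFrame(
                    {"level": level, "coast_km": s["coast_km"], "n_points": s["n_points"]}
                )
            base[f"km_higher_{scen}"] = s["coast_km_higher"]
            base[f"pct_higher_{scen}"] = s["pct_higher"].map(round_half_up)
            base[f"mean_ie_{scen}"] = s["mean_ie"].map(lambda v: round_half_up(v, 2))
            if population and scen in population and level in population[scen]:
                p = population[scen][level].set_index("unit_id")
                base[f"population_higher_{scen}"] = p["population_higher"].reindex(base.index)
        base = base.reset_index()
        base["name"] = base["unit_id"].map(lambda u: names.get(u, "All") if u != 0 else names.get(0, "Region"))
        frames.append(base)
    out = pd.concat(frames, ignore_index=True)
    lead = ["unit_id", "level", "name", "coast_km", "n_points"]
    return out[lead + [c for c in out.columns if c not in lead]]
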