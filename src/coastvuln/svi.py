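"""District-level social vulnerability index (SVI).

Eight census indicators (age structure, growth, density, illiteracy, housing
and sanitation standards) are log-transformed, standardised to z-scores
across the included districts, summed according to the direction of each
indicator's influence on vulnerability (all eight increase it by default),
and the resulting scores are ranked 1 (first quintile, very low social
vulnerability) to 5 (fifth quintile, very high).

Districts with any missing indicator are excluded from the standardisation
and get no SVI — mirroring how units without comparable census data drop out
of the downstream vulnerability index rather than receiving an imputed score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import rank_quantile

#: The eight census indicator columns, in canonical order.
INDICATORS = [
    "pct_under4",
    "pct_over65",
    "pct_annual_growth",
    "density_per_km2",
    "pct_illiterate",
    "pct_natural_housing",
    "pct_unimproved_water",
    "pct_unimproved_waste",
]


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    direction: int = +1  # +1: larger value -> more vulnerable

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


DEFAULT_INDICATOR_SPECS = tuple(IndicatorSpec(name) for name in INDICATORS)


def transform_indicator(values, offset: float = 1.0) -> np.ndarray:
    """ln(v + offset), then z-score with sample (n-1) standard deviation.

    The unit offset admits zero-valued percentages; pass ``offset=0`` for
    strictly positive data (in that configuration rescaling all raw values
    by a constant leaves the z-scores unchanged).  A constant column has no
    spread and maps to all-zero z-scores.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 districts to standardise")
    if (arr < 0).any():
        raise ValueError("census indicator values must be non-negative")
    logv = np.log(arr + offset)
    sd = logv.std(ddof=1)
    if sd == 0:
        return np.zeros_like(logv)
    return (logv - logv.mean()) / sd


def compute_svi(
    census: pd.DataFrame,
    indicator_specs=DEFAULT_INDICATOR_SPECS,
    offset: float = 1.0,
) -> pd.DataFrame:
    """SVI scores and quintile ranks for every complete district.

    Returns a table with district_id, one ``z_<indicator>`` column per
    indicator, the direction-weighted sum ``score``, and ``svi_rank`` 1-5
    (quintile breakpoints at the 20/40/60/80th percentiles of the scores,
    ties to the lower class).  Incomplete districts are reported in the
    ``excluded`` attribute (a list of district ids), not failed.
    """
    names = [s.name for s in indicator_specs]
    missing = [n for n in names if n not in census.columns]
    if missing:
        raise ValueError(f"census table missing indicator columns: {missing}")
    complete = census.dropna(subset=names)
    excluded = sorted(set(census["district_id"]) - set(complete["district_id"]))
    if len(complete) < 5:
        raise ValueError(
            f"need >= 5 complete districts to compute the SVI, "
            f"got {len(complete)} (excluded: {excluded})"
        )
    out = pd.DataFrame({"district_id": complete["district_id"].to_numpy()})
    score = np.zeros(len(complete))
    for spec in indicator_specs:
        z = transform_indicator(complete[spec.name].to_numpy(), offset)
        out[f"z_{spec.name}"] = z
        score += spec.direction * z
    out["score"] = score
    out["svi_rank"] = rank_quantile(score)
    out.attrs["excluded"] = excluded
    return out


def province_svi(svi_scores: pd.DataFrame, hierarchy: pd.DataFrame) -> pd.Series:
    """Mean district SVI rank per province.

    Ranks (1-5), not raw scores, are averaged; provinces with no scored
    district are absent from the result.
    """
    d2p = {
        int(r.unit_id): int(r.parent_id)
        for r in hierarchy[hierarchy["level"] == "district"].itertuples()
    }
    df = svi_scores[["district_id", "svi_rank"]].copy()
    df["province_id"] = [d2p[int(d)] for d in df["district_id"]]
    return df.groupby("province_id")["svi_rank"].mean().rename("svi")
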