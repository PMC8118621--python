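"""Nonparametric validation of the exposure and vulnerability indices.

The indices are validated against independently recorded coastal hazard
events per district (DesInventar-style counts of events and of events causing
fatalities).  Districts are split into 'exposed' and 'less exposed' at a
series of thresholds on the percentage of shoreline points at higher
exposure under current conditions; Mann-Whitney U tests compare event counts
between the two groups, and Spearman rank correlations relate the continuous
%-at-H (and the IVCC) to the counts.  Event counts are heavily skewed, hence
the rank-based tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (20.0, 25.0, 30.0, 50.0)


@dataclass
class ValidationResult:
    """Test results at one exposed/less-exposed threshold."""

    threshold_pct: float
    n_exposed: int
    n_less: int
    u_events: float
    p_events: float
    u_fatal: float
    p_fatal: float
    rho: dict = field(default_factory=dict)  # label -> (rho, p)


def classify_exposed(pct_higher, threshold_pct: float) -> np.ndarray:
    """Exposed iff the % of shoreline points at H meets the threshold.

    The comparison is inclusive (>=), following the convention of
    classifying districts with at least the stated share of points at
    higher exposure as 'exposed'.
    """
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError(f"threshold must lie in (0, 100), got {threshold_pct}")
    return np.asarray(pct_higher, dtype=float) >= threshold_pct


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U of group_a (two-sided).

    U is computed from midranks; U + U' = n_a * n_b.  The p-value uses
    exact enumeration for small samples (n_a*n_b <= 20, no ties) and the
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks, tie-safe) with two-sided p.

    The p-value comes from the t approximation with n-2 degrees of
    freedom.  Zero variance in either vector leaves rho undefined: the
    result is (nan, nan) with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("spearman_rho: zero variance input, rho undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def run_validation(
    admin_summaries: pd.DataFrame,
    events: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    pct_col: str = "pct_higher_S1_all",
    ivcc_col: str | None = "ivcc_S1_all",
) -> list[ValidationResult]:
    """Run the full validation protocol over the given thresholds.

    ``admin_summaries`` needs unit_id and the % at higher exposure under
    current conditions (and optionally the IVCC); ``events`` needs
    unit_id, n_events, n_fatal_events.  Units present on only one side are
    dropped with a logged count.
    """
    df = admin_summaries.merge(events, on="unit_id", how="inner")
    n_dropped = (len(admin_summaries) - len(df)) + (len(events) - len(df))
    if n_dropped:
        logger.warning("run_validation: %d unmatched unit(s) dropped", n_dropped)
    if df.empty:
        raise ValueError("no overlapping units between summaries and events")
    if (df["n_fatal_events"] > df["n_events"]).any():
        raise ValueError("n_fatal_events exceeds n_events for some unit")
    pct = df[pct_col].to_numpy()

    def _rho(x, y):
        if len(x) < 3:
            logger.warning("run_validation: < 3 units, Spearman skipped")
            return float("nan"), float("nan")
        return spearman_rho(x, y)

    rho_common = {
        "pct_vs_events": _rho(pct, df["n_events"]),
        "pct_vs_fatal": _rho(pct, df["n_fatal_events"]),
    }
    if ivcc_col is not None and ivcc_col in df.columns:
        sub = df.dropna(subset=[ivcc_col])
        if len(sub) >= 3:
            rho_common["ivcc_vs_events"] = spearman_rho(sub[ivcc_col], sub["n_events"])
            rho_common["ivcc_vs_fatal"] = spearman_rho(sub[ivcc_col], sub["n_fatal_events"])
    results = []
    for thr in thresholds:
        exposed = classify_exposed(pct, thr)
        a = df.loc[exposed]
        b = df.loc[~exposed]
        if len(a) and len(b):
            u_e, p_e = mann_whitney_u(a["n_events"], b["n_events"])
            u_f, p_f = mann_whitney_u(a["n_fatal_events"], b["n_fatal_events"])
        else:
            logger.warning("threshold %.0f%%: one group empty, U test skipped", thr)
            u_e = p_e = u_f = p_f = float("nan")
        results.append(
            ValidationResult(
                threshold_pct=float(thr),
                n_exposed=int(exposed.sum()),
                n_less=int((~exposed).sum()),
                u_events=u_e,
                p_events=p_e,
                u_fatal=u_f,
                p_fatal=p_f,
                rho=dict(rho_common),
            )
        )
    return results


def validation_table(results: list[ValidationResult]) -> pd.DataFrame:
    """Flatten ValidationResult list to a report table."""
    rows = []
    for r in results:
        row = {
            "threshold_pct": r.threshold_pct,
            "n_exposed": r.n_exposed,
            "n_less": r.n_less,
            "u_events": r.u_events,
            "p_events": r.p_events,
            "u_fatal": r.u_fatal,
            "p_fatal": r.p_fatal,
        }
        for label, (rho, p) in r.rho.items():
            row[f"rho_{label}"] = rho
            row[f"p_{label}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
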