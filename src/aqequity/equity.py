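"""Population-weighted exposure and disparity metrics.

Each person is assigned their county's annual PM2.5-equivalent
concentration.  A group's population-weighted exposure is the
population-weighted mean of county concentrations over that group;
its *disparity* is the group exposure minus the total-population
exposure (negative means below-average exposure).  By construction
the population-weighted sum of group disparities is exactly zero.
Distributional summaries use population-weighted quantiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import GROUPS

QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


def _group_pop(pop: pd.DataFrame, group, period: int) -> pd.Series:
    p = pop[pop["period"] == period]
    if group != "total":
        p = p[p["group"] == group]
    return p.groupby("county_id")["persons"].sum()


def pw_exposure(field: pd.DataFrame, pop: pd.DataFrame, group, period: int) -> float:
    """Population-weighted mean exposure for a group (or ``"total"``).

    ``field`` columns: county_id, period, conc.  Requires the field
    and population to cover identical county sets for the period.
    """
    f = field[field["period"] == period].groupby("county_id")["conc"].sum()
    w = _group_pop(pop, group, period)
    if set(f.index) != set(w.index):
        raise ValueError("field and population cover different county sets")
    total = w.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} has zero population in {period}")
    w = w.reindex(f.index)
    return float((f * w).sum() / total)


def disparity(field: pd.DataFrame, pop: pd.DataFrame, group: str, period: int) -> float:
    """Group population-weighted exposure minus the total-population
    exposure; may be negative."""
    return pw_exposure(field, pop, group, period) - pw_exposure(field, pop, "total", period)


def weighted_quantile(values, weights, q: float, method: str = "midpoint") -> float:
    """Population-weighted quantile of county values.

    Two conventions are supported (the choice of estimator for
    distributional summaries is a config matter, not a modelling one):

    * ``"midpoint"`` (default) — linear interpolation through the
      weighted midpoint positions (cum - w/2) / total; with equal
      weights on {1, 2, 3}, q = 0.5 returns the middle value 2.
    * ``"inverted_cdf"`` — the smallest value whose cumulative
      normalised weight reaches q (a pure step rule, no
      interpolation).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    if method == "inverted_cdf":
        idx = int(np.searchsorted(cw / cw[-1], q, side="left"))
        return float(v[min(idx, len(v) - 1)])
    if method != "midpoint":
        raise ValueError(f"unknown quantile method {method!r}")
    pk = (cw - 0.5 * w) / cw[-1]
    if q <= pk[0]:
        return float(v[0])
    if q >= pk[-1]:
        return float(v[-1])
    return float(np.interp(q, pk, v))


def exposure_summary(
    field: pd.DataFrame,
    pop: pd.DataFrame,
    periods=None,
    quantiles=QUANTILES,
) -> pd.DataFrame:
    """Tidy exposure summary across groups and periods.

    One row per (period, group, metric): population-weighted mean,
    disparity, and weighted quantiles, for each race-ethnicity group
    and for the total population.
    """
    if periods is None:
        periods = sorted(field["period"].unique())
    rows = []
    for period in periods:
        f = field[field["period"] == period].groupby("county_id")["conc"].sum()
        tot = pw_exposure(field, pop, "total", period)
        for group in list(GROUPS) + ["total"]:
            w = _group_pop(pop, group, period).reindex(f.index, fill_value=0.0)
            mean = pw_exposure(field, pop, group, period)
            rows.append({"period": period, "group": group, "metric": "pw_exposure", "value": mean})
            rows.append({"period": period, "group": group, "metric": "disparity", "value": mean - tot})
            for q in quantiles:
                rows.append(
                    {
                        "period": period,
                        "group": group,
                        "metric": f"q{int(round(q * 100))}",
                        "value": weighted_quantile(f.to_numpy(), w.to_numpy(), q),
                    }
                )
    return pd.DataFrame(rows)
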