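"""Concentration-response mortality model.

Expected premature mortality from a PM2.5 change follows the standard
log-linear health-impact form

    dMort = y0 * Pop * (1 - exp(-beta * dPM)),

applied per county, race-ethnicity group and adult age band (30+),
with beta = ln(RR) / 10 for a relative risk stated per 10 µg/m³.
Three estimate variants bracket the uncertainty in how risk varies
by race:

* **A** — one constant relative risk and all-person (race-collapsed)
  age-specific baseline mortality;
* **B** — constant relative risk, race- and age-specific baseline
  mortality;
* **C** — race-specific relative risk (expressed as multipliers on
  ln RR) and race- and age-specific baseline mortality.

Cumulative deaths weight each five-year model period by the years it
represents (5 for 2020-2045, 1 for 2050: a 31-year 2020-2050
horizon); avoided deaths are baseline-scenario deaths minus policy
deaths, reported as the (min, max) range over the three variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import ADULT_BANDS, GROUPS, PERIODS

VARIANTS = ["A", "B", "C"]

# Default annual baseline mortality rates (deaths per person-year) by
# race and adult age band.  Config placeholders with realistic
# magnitudes and ordering: rates rise with age; the Hispanic rows are
# lowest (the "Hispanic paradox" pattern in all-cause mortality).
DEFAULT_MORTALITY = {
    ("white_nh", "30-64"): 0.0045,
    ("white_nh", "65-79"): 0.025,
    ("white_nh", "80+"): 0.13,
    ("black_nh", "30-64"): 0.0060,
    ("black_nh", "65-79"): 0.030,
    ("black_nh", "80+"): 0.14,
    ("hispanic", "30-64"): 0.0030,
    ("hispanic", "65-79"): 0.018,
    ("hispanic", "80+"): 0.11,
    ("other", "30-64"): 0.0035,
    ("other", "65-79"): 0.020,
    ("other", "80+"): 0.12,
}

# Year weights for the cumulative 2020-2050 horizon (31 years).
PERIOD_YEARS = {p: (5 if p < 2050 else 1) for p in PERIODS}


def beta_from_rr(rr: float, delta_c: float = 10.0) -> float:
    """Risk coefficient per µg/m³: beta = ln(RR) / delta_c."""
    if rr <= 0 or delta_c <= 0:
        raise ValueError("rr and delta_c must be positive")
    return float(np.log(rr) / delta_c)


@dataclass(frozen=True)
class RelativeRiskConfig:
    """Relative-risk configuration for the three variants.

    ``rr_constant`` is the all-group RR per 10 µg/m³ (single
    cohort-study convention).  ``race_beta_multiplier`` scales ln(RR)
    per group for variant C (race-stratified convention); a multiplier
    of 3 triples the small-signal mortality response.  All values are
    configuration placeholders, not empirical estimates.
    """

    rr_constant: float = 1.06
    race_beta_multiplier: dict = field(
        default_factory=lambda: {
            "black_nh": 3.0,
            "white_nh": 0.9,
            "hispanic": 1.2,
            "other": 1.2,
        }
    )

    def beta(self, variant: str, group: str) -> float:
        b = beta_from_rr(self.rr_constant)
        if variant in ("A", "B"):
            return b
        if variant == "C":
            return b * self.race_beta_multiplier[group]
        raise ValueError(f"unknown variant {variant!r}")


@dataclass
class MortalityRates:
    """Baseline mortality rates y0 by (race, adult age band).

    ``collapse_races(pop)`` returns the all-person variant: one
    age-specific rate shared by every race, formed as the
    population-weighted average of the race-specific rates (so a
    degenerate table where all races share rates collapses to
    itself).
    """

    y0: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY))

    def __post_init__(self):
        for (g, band), v in self.y0.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mortality rate out of [0,1] for {(g, band)}")

    def rate(self, group: str, band: str) -> float:
        return self.y0[(group, band)]

    def collapse_races(self, pop: pd.DataFrame, period: int = 2020) -> "MortalityRates":
        p = pop[(pop["period"] == period) & (pop["age_band"].isin(ADULT_BANDS))]
        by = p.groupby(["group", "age_band"])["persons"].sum()
        collapsed = {}
        for band in ADULT_BANDS:
            num = sum(self.y0[(g, band)] * by.get((g, band), 0.0) for g in GROUPS)
            den = sum(by.get((g, band), 0.0) for g in GROUPS)
            rate = num / den if den > 0 else float(np.mean([self.y0[(g, band)] for g in GROUPS]))
            for g in GROUPS:
                collapsed[(g, band)] = rate
        return MortalityRates(y0=collapsed)


def delta_mortality(delta_pm, y0, beta, pop):
    """dMort = y0 * pop * (1 - exp(-beta * dPM)).

    Continuous, increasing and concave in dPM for beta > 0, bounded
    above by y0 * pop, and first-order y0 * pop * beta * dPM for small
    signals.
    """
    y0 = np.asarray(y0, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if (pop < 0).any():
        raise ValueError("population must be nonnegative")
    if ((y0 < 0) | (y0 > 1)).any():
        raise ValueError("baseline mortality rates must lie in [0, 1]")
    return y0 * pop * -np.expm1(-beta * np.asarray(delta_pm, dtype=float))


def scenario_deaths(
    field: pd.DataFrame,
    pop: pd.DataFrame,
    rates: MortalityRates,
    rrconf: RelativeRiskConfig,
    variants=VARIANTS,
) -> pd.DataFrame:
    """Expected deaths by county, group, period and variant.

    Variant A forces race-collapsed baseline rates (computed from the
    2020 adult population); B and C use the race-specific table.
    Deaths accrue only to the 30+ age bands.

    Returns ``county_id, group, period, variant, deaths`` (annual
    deaths in each period).
    """
    rates_a = rates.collapse_races(pop)
    conc = field.groupby(["county_id", "period"])["conc"].sum()
    adults = pop[pop["age_band"].isin(ADULT_BANDS)]
    out = []
    for variant in variants:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        r = rates_a if variant == "A" else rates
        sub = adults.copy()
        sub["y0"] = [r.rate(g, b) for g, b in zip(sub["group"], sub["age_band"])]
        sub["beta"] = [rrconf.beta(variant, g) for g in sub["group"]]
        sub["dpm"] = [
            conc.get((c, p), 0.0) for c, p in zip(sub["county_id"], sub["period"])
        ]
        sub["deaths"] = delta_mortality(sub["dpm"], sub["y0"], sub["beta"], sub["persons"])
        g = sub.groupby(["county_id", "group", "period"], as_index=False)["deaths"].sum()
        g["variant"] = variant
        out.append(g)
    return pd.concat(out, ignore_index=True)[
        ["county_id", "group", "period", "variant", "deaths"]
    ]


def cumulative_deaths(deaths: pd.DataFrame, period_years: dict | None = None) -> pd.Series:
    """Cumulative 2020-2050 deaths per variant (annual deaths times
    the years each period represents)."""
    w = period_years or PERIOD_YEARS
    d = deaths.copy()
    d["wdeaths"] = d["deaths"] * d["period"].map(w)
    return d.groupby("variant")["wdeaths"].sum()


def avoided_deaths(
    policy: pd.DataFrame, baseline: pd.DataFrame, period_years: dict | None = None
) -> dict:
    """Cumulative avoided deaths of a policy vs the baseline scenario.

    Returns ``{"by_variant": {v: avoided}, "min": ..., "max": ...}``
    where the range is the min-max over the three estimate variants.
    """
    for col in ("county_id", "group", "period"):
        if set(policy[col].unique()) != set(baseline[col].unique()):
            raise ValueError(f"policy and baseline differ in {col} universe")
    cp = cumulative_deaths(policy, period_years)
    cb = cumulative_deaths(baseline, period_years)
    avoided = (cb - cp).to_dict()
    return {"by_variant": avoided, "min": min(avoided.values()), "max": max(avoided.values())}


def per_capita_deaths(
    deaths: pd.DataFrame, pop: pd.DataFrame, group: str, period: int, variant: str = "B"
) -> float:
    """Deaths per 100,000 group members (all ages) in a period."""
    d = deaths[
        (deaths["group"] == group)
        & (deaths["period"] == period)
        & (deaths["variant"] == variant)
    ]["deaths"].sum()
    p = pop[(pop["group"] == group) & (pop["period"] == period)]["persons"].sum()
    if p <= 0:
        raise ValueError(f"group {group!r} has zero population in {period}")
    return float(d / p * 1e5)
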