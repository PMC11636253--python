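"""Synthetic inputs for the policy-to-exposure pipeline.

This module generates every input the analysis consumes, with the
structural and statistical properties the downstream stages assume:

* a planar multi-region county geography (receptors are
  population-weighted county centroids),
* an SSP2-like county population projection by race-ethnicity group and
  age band (total +20% over 2020-2050; the White non-Hispanic share
  falling from 60% to 48% while Hispanic, Black non-Hispanic and Other
  shares rise),
* an electricity-generating-unit (EGU) fleet organised into dispatch
  clusters, with planned units and retired sites for grow-in-place
  siting,
* a county vehicle-miles-travelled (VMT) spatial surrogate for the
  surrogate years 2023/2026/2032 plus national scaling factors for
  later periods,
* a vehicle-stock cohort model, and
* stylized regional emission trajectories for six policy scenarios
  (current policy, clean electricity standard, carbon tax, ICE ban,
  ICE ban + CES, net-zero), standing in for a full energy-system
  optimisation model.

All generators are deterministic for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical label sets used across the package.
GROUPS = ["black_nh", "white_nh", "hispanic", "other"]
AGE_BANDS = ["0-29", "30-64", "65-79", "80+"]
ADULT_BANDS = ["30-64", "65-79", "80+"]  # mortality applies to ages 30+
PERIODS = list(range(2020, 2055, 5))
POLLUTANTS = ["NOx", "SO2", "PM2.5"]
VEHICLE_CLASSES = ["ldv", "mhdv"]
SURROGATE_YEARS = [2023, 2026, 2032]
SCENARIOS = [
    "current_policy",
    "ces",
    "carbon_tax",
    "ice_ban",
    "ice_ban_ces",
    "net_zero",
]

# Fixed age pyramids (fraction of group population per band).  Hispanic
# and Other populations skew younger than White non-Hispanic; the White
# non-Hispanic pyramid is the oldest, which matters for mortality.
AGE_PYRAMID = {
    "white_nh": {"0-29": 0.33, "30-64": 0.45, "65-79": 0.15, "80+": 0.07},
    "black_nh": {"0-29": 0.41, "30-64": 0.44, "65-79": 0.11, "80+": 0.04},
    "hispanic": {"0-29": 0.46, "30-64": 0.43, "65-79": 0.08, "80+": 0.03},
    "other": {"0-29": 0.42, "30-64": 0.44, "65-79": 0.10, "80+": 0.04},
}


@dataclass(frozen=True)
class DemographicTrajectory:
    """National demographic anchors for 2020 and 2050.

    ``total_growth_2050`` is the fractional national population growth
    between 2020 and 2050 (0.20 means +20%).  ``group_share_anchors``
    maps each race-ethnicity group to its (2020, 2050) national
    population shares; shares are linearly interpolated in between.
    """

    total_growth_2050: float = 0.20
    group_share_anchors: dict = field(
        default_factory=lambda: {
            # White, Hispanic and Black non-Hispanic shares are the
            # published SSP2 endpoints; "Other" absorbs the rounding
            # residual so shares sum to exactly 1 at both anchors.
            "white_nh": (0.60, 0.48),
            "hispanic": (0.18, 0.25),
            "black_nh": (0.13, 0.14),
            "other": (0.09, 0.13),
        }
    )

    def __post_init__(self):
        if self.total_growth_2050 < -1:
            raise ValueError("total growth below -100% is not meaningful")
        for year_idx in (0, 1):
            s = sum(v[year_idx] for v in self.group_share_anchors.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"group shares must sum to 1 at each anchor (got {s})"
                )

    def national_total(self, base_total: float, period: int) -> float:
        """National population in ``period`` under linear growth."""
        return base_total * (1.0 + self.total_growth_2050 * (period - 2020) / 30.0)

    def group_share(self, group: str, period: int) -> float:
        s0, s1 = self.group_share_anchors[group]
        w = (period - 2020) / 30.0
        return s0 + (s1 - s0) * w


@dataclass(frozen=True)
class PolicySchedule:
    """Stylized policy levers by five-year period.

    ``ces_clean_fraction`` is the minimum clean share of electricity
    generation; ``zev_sales_share`` the zero-emission share of new
    vehicle sales per class; ``carbon_tax`` in $/t CO2;
    ``netzero_cap_fraction`` the allowed fraction of 2020 emissions
    under a linear net-zero cap.
    """

    name: str
    ces_clean_fraction: dict = field(default_factory=dict)
    zev_sales_share: dict = field(default_factory=dict)  # (class, period) -> frac
    carbon_tax: dict = field(default_factory=dict)
    netzero_cap_fraction: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.ces_clean_fraction, self.netzero_cap_fraction):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("schedule fractions must lie in [0, 1]")
        for v in self.zev_sales_share.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("ZEV sales shares must lie in [0, 1]")
        # CES and per-class ZEV schedules must be nondecreasing.
        vals = [self.ces_clean_fraction[p] for p in sorted(self.ces_clean_fraction)]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("ces_clean_fraction must be nondecreasing")
        for cls in {k[0] for k in self.zev_sales_share}:
            vals = [
                self.zev_sales_share[(cls, p)]
                for p in sorted(p for c, p in self.zev_sales_share if c == cls)
            ]
            if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError("zev_sales_share must be nondecreasing per class")


def _interp_schedule(points: dict[int, float]) -> dict[int, float]:
    """Fill all model periods by linear interpolation between anchors."""
    years = sorted(points)
    vals = [points[y] for y in years]
    return {
        p: float(np.interp(p, years, vals)) for p in PERIODS
    }


def default_schedule(name: str) -> PolicySchedule:
    """Construct the stylized schedule for one of the six policies.

    CES: 80% clean electricity in 2030 rising linearly to 100% in 2050.
    Carbon tax: effective 2025, rising from $50 to $80 /t CO2 by 2050.
    ICE ban: 80% ZEV light-duty sales in 2030 and 100% from 2035; 35%
    medium/heavy-duty in 2030 rising linearly to 100% by 2045.
    Net-zero: linear decline from 2020 emissions to zero in 2050.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    # Baseline ZEV adoption outside an ICE ban: gentle market-driven
    # uptake reaching 30% of LDV sales and 15% of MHDV sales by 2050.
    baseline_zev = {
        ("ldv", p): v for p, v in _interp_schedule({2020: 0.0, 2050: 0.30}).items()
    }
    baseline_zev.update(
        {("mhdv", p): v for p, v in _interp_schedule({2020: 0.0, 2050: 0.15}).items()}
    )
    ban_zev = {
        ("ldv", p): v
        for p, v in _interp_schedule({2020: 0.0, 2025: 0.1, 2030: 0.8, 2035: 1.0, 2050: 1.0}).items()
    }
    ban_zev.update(
        {
            ("mhdv", p): v
            for p, v in _interp_schedule({2020: 0.0, 2025: 0.05, 2030: 0.35, 2045: 1.0, 2050: 1.0}).items()
        }
    )
    ces = _interp_schedule({2020: 0.0, 2025: 0.0, 2030: 0.8, 2050: 1.0})
    tax = _interp_schedule({2020: 0.0, 2024: 0.0, 2025: 50.0, 2050: 80.0})
    cap = _interp_schedule({2020: 1.0, 2050: 0.0})

    if name == "current_policy":
        return PolicySchedule(name=name, zev_sales_share=baseline_zev)
    if name == "ces":
        return PolicySchedule(name=name, ces_clean_fraction=ces, zev_sales_share=baseline_zev)
    if name == "carbon_tax":
        return PolicySchedule(name=name, carbon_tax=tax, zev_sales_share=baseline_zev)
    if name == "ice_ban":
        return PolicySchedule(name=name, zev_sales_share=ban_zev)
    if name == "ice_ban_ces":
        return PolicySchedule(name=name, ces_clean_fraction=ces, zev_sales_share=ban_zev)
    if name == "net_zero":
        return PolicySchedule(name=name, netzero_cap_fraction=cap, zev_sales_share=baseline_zev)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def gen_counties(
    n_regions: int, counties_per_region: int, domain_size: float, seed: int
) -> pd.DataFrame:
    """Generate a planar county geography on a square domain.

    Counties tile a near-square grid covering a ``domain_size`` x
    ``domain_size`` km square; consecutive grid cells form contiguous
    region blocks.  The population-weighted centroid is the geometric
    centroid jittered by up to a quarter cell in each axis.

    Returns a DataFrame with columns ``county_id`` (FIPS-like string),
    ``region_id`` (1-based int), ``cx``/``cy`` (geometric centroid,
    km), ``area`` (km^2) and ``pw_x``/``pw_y`` (population-weighted
    centroid, km).
    """
    if n_regions < 1 or counties_per_region < 1 or domain_size <= 0:
        raise ValueError("n_regions, counties_per_region and domain_size must be positive")
    rng = np.random.default_rng(seed)
    n = n_regions * counties_per_region
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    dx = domain_size / ncols
    dy = domain_size / nrows
    # Cells in the last (partial) row absorb the leftover height so the
    # domain area is covered exactly.
    rows = []
    for k in range(n):
        r, c = divmod(k, ncols)
        cells_in_row = ncols if (r < nrows - 1 or n % ncols == 0) else n % ncols
        width = domain_size / cells_in_row
        cx = (c + 0.5) * width
        cy = (r + 0.5) * dy
        area = width * dy
        region = k // counties_per_region + 1
        jx = rng.uniform(-0.25, 0.25) * width
        jy = rng.uniform(-0.25, 0.25) * dy
        rows.append(
            {
                "county_id": f"{region:02d}{(k % counties_per_region) + 1:03d}",
                "region_id": region,
                "cx": cx,
                "cy": cy,
                "area": area,
                "pw_x": cx + jx,
                "pw_y": cy + jy,
            }
        )
    df = pd.DataFrame(rows)
    assert df["county_id"].is_unique
    return df


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def _ipf(seed_matrix: np.ndarray, row_targets: np.ndarray, col_targets: np.ndarray,
         n_iter: int = 200, tol: float = 1e-13) -> np.ndarray:
    """Iterative proportional fitting with a final column scaling, so
    column (group) totals are matched exactly."""
    m = seed_matrix.astype(float).copy()
    for _ in range(n_iter):
        rs = m.sum(axis=1)
        m *= (row_targets / np.where(rs > 0, rs, 1.0))[:, None]
        cs = m.sum(axis=0)
        m *= (col_targets / np.where(cs > 0, cs, 1.0))[None, :]
        if np.max(np.abs(m.sum(axis=1) - row_targets) / row_targets.sum()) < tol:
            break
    cs = m.sum(axis=0)
    m *= (col_targets / np.where(cs > 0, cs, 1.0))[None, :]
    return m


def gen_population(
    counties: pd.DataFrame,
    traj: DemographicTrajectory,
    base_total: float,
    seed: int,
) -> pd.DataFrame:
    """Generate the county population projection.

    2020 county totals follow a heavy-tailed (log-normal) size
    distribution, so a few counties are dense.  Per-county group mixes
    are drawn around the national anchors and then balanced by
    iterative proportional fitting so that national group shares match
    the trajectory anchors (exactly at the column-scaling step) in
    every period, while county totals keep their fixed share of the
    growing national population.  Age bands apply a fixed per-group
    pyramid.

    Returns a tidy DataFrame ``county_id, group, age_band, period,
    persons``.
    """
    if len(counties) == 0:
        raise ValueError("county set must be non-empty")
    if base_total <= 0:
        raise ValueError("base_total must be positive")
    rng = np.random.default_rng(seed)
    n = len(counties)
    sizes = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    county_weight = sizes / sizes.sum()

    # County-level propensity multipliers per group: spatial sorting of
    # groups across counties, fixed over time.
    propensity = rng.lognormal(mean=0.0, sigma=0.6, size=(n, len(GROUPS)))

    recs = []
    for period in PERIODS:
        ntot = traj.national_total(base_total, period)
        row_t = county_weight * ntot
        col_t = np.array([traj.group_share(g, period) for g in GROUPS]) * ntot
        seed_m = (county_weight[:, None]) * np.array(
            [traj.group_share(g, period) for g in GROUPS]
        )[None, :] * propensity
        m = _ipf(seed_m, row_t, col_t)
        for gi, g in enumerate(GROUPS):
            pyramid = AGE_PYRAMID[g]
            for band in AGE_BANDS:
                recs.append(
                    pd.DataFrame(
                        {
                            "county_id": counties["county_id"].to_numpy(),
                            "group": g,
                            "age_band": band,
                            "period": period,
                            "persons": m[:, gi] * pyramid[band],
                        }
                    )
                )
    pop = pd.concat(recs, ignore_index=True)
    assert (pop["persons"] >= 0).all()
    return pop


# ---------------------------------------------------------------------------
# EGU fleet
# ---------------------------------------------------------------------------

def gen_egu_fleet(
    counties: pd.DataFrame, n_clusters: int, units_per_cluster: int, seed: int
) -> pd.DataFrame:
    """Generate the synthetic EGU fleet.

    Clusters are assigned round-robin to regions; each cluster's units
    sit in counties of that one region.  2020 generation is drawn
    log-normally.  Each region also receives at least one planned unit
    and one retired-site record (zero 2020 generation), which seed the
    grow-in-place siting tiers.  All existing fossil units default to
    the medium effective-height bin.

    Returns a DataFrame ``unit_id, plant_id, cluster_id, county_id,
    fuel, capacity_mw, gen_2020_mwh, status, height_bin``.
    """
    if n_clusters < 1 or units_per_cluster < 1:
        raise ValueError("n_clusters and units_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    regions = sorted(counties["region_id"].unique())
    by_region = {r: counties.loc[counties["region_id"] == r, "county_id"].to_numpy() for r in regions}
    rows = []
    uid = 0
    for ci in range(n_clusters):
        region = regions[ci % len(regions)]
        fuel = "coal" if rng.random() < 0.4 else "gas"
        for _ in range(units_per_cluster):
            county = rng.choice(by_region[region])
            # ~3.3 TWh/yr median per unit: the scale of a mid-size
            # fossil plant, so sector emission shares are realistic.
            gen = float(rng.lognormal(mean=15.0, sigma=1.0))  # MWh
            cap = gen / (0.5 * 8760.0)
            rows.append(
                {
                    "unit_id": f"U{uid:04d}",
                    "plant_id": f"P{uid // 2:04d}",
                    "cluster_id": f"C{ci:03d}",
                    "county_id": county,
                    "fuel": fuel,
                    "capacity_mw": cap,
                    "gen_2020_mwh": gen,
                    "status": "existing",
                    "height_bin": "medium",
                }
            )
            uid += 1
    # Planned units and retired sites: one or more per region.
    for region in regions:
        n_planned = 1 + int(rng.random() < 0.5)
        for _ in range(n_planned):
            county = rng.choice(by_region[region])
            rows.append(
                {
                    "unit_id": f"U{uid:04d}",
                    "plant_id": f"P{uid:04d}",
                    "cluster_id": f"PLAN{region:02d}",
                    "county_id": county,
                    "fuel": "gas",
                    "capacity_mw": float(rng.uniform(100, 500)),
                    "gen_2020_mwh": 0.0,
                    "status": "planned",
                    "height_bin": "medium",
                }
            )
            uid += 1
        n_retired = 1 + int(rng.random() < 0.5)
        for _ in range(n_retired):
            county = rng.choice(by_region[region])
            rows.append(
                {
                    "unit_id": f"U{uid:04d}",
                    "plant_id": f"P{uid:04d}",
                    "cluster_id": f"RET{region:02d}",
                    "county_id": county,
                    "fuel": "coal" if rng.random() < 0.5 else "gas",
                    "capacity_mw": float(rng.uniform(100, 800)),
                    "gen_2020_mwh": 0.0,
                    "status": "retired_site",
                    "height_bin": "medium",
                }
            )
            uid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VMT surrogate
# ---------------------------------------------------------------------------

@dataclass
class VMTSurrogate:
    """County VMT by vehicle type for the surrogate years, plus the
    national scaling factors (relative to the 2032 surrogate) used for
    periods 2035 onward."""

    vmt: pd.DataFrame  # county_id, vehicle_type, surrogate_year, vmt
    national_scale: pd.DataFrame  # vehicle_type, period, factor


def gen_vmt_surrogate(
    counties: pd.DataFrame, population: pd.DataFrame, seed: int
) -> VMTSurrogate:
    """Generate the county VMT surrogate.

    County VMT is proportional to 2020 county population times a
    seeded urban/rural multiplier (denser counties drive somewhat less
    per capita), for each vehicle type and surrogate year.  National
    scaling factors for 2035-2050 are drawn in [0.9, 1.3].
    """
    pop20 = (
        population[population["period"] == 2020]
        .groupby("county_id")["persons"].sum()
        .reindex(counties["county_id"])
    )
    if pop20.isna().any():
        raise ValueError("population table must cover 2020 for every county")
    rng = np.random.default_rng(seed)
    mult = rng.uniform(0.7, 1.3, size=len(counties))
    per_capita = {"ldv": 9000.0, "mhdv": 1200.0}  # miles / person / yr
    year_growth = {2023: 1.0, 2026: 1.03, 2032: 1.08}
    rows = []
    for vt in VEHICLE_CLASSES:
        base = pop20.to_numpy() * mult * per_capita[vt]
        for yr in SURROGATE_YEARS:
            rows.append(
                pd.DataFrame(
                    {
                        "county_id": counties["county_id"].to_numpy(),
                        "vehicle_type": vt,
                        "surrogate_year": yr,
                        "vmt": base * year_growth[yr],
                    }
                )
            )
    scale_rows = []
    for vt in VEHICLE_CLASSES:
        for p in [p for p in PERIODS if p >= 2035]:
            scale_rows.append(
                {"vehicle_type": vt, "period": p, "factor": float(rng.uniform(0.9, 1.3))}
            )
    return VMTSurrogate(
        vmt=pd.concat(rows, ignore_index=True),
        national_scale=pd.DataFrame(scale_rows),
    )


# ---------------------------------------------------------------------------
# Vehicle stock turnover
# ---------------------------------------------------------------------------

def fleet_turnover(
    schedule: PolicySchedule,
    initial_stock: pd.DataFrame,
    lifetime: int,
    sales_per_period: dict[str, float],
) -> pd.DataFrame:
    """Cohort vehicle-stock model.

    A cohort of vintage period ``v`` stays on the road through period
    ``v + 5*lifetime`` inclusive (``lifetime`` counted in five-year
    periods), then retires.  New sales each period are split between
    ICE and ZEV by the schedule's ``zev_sales_share``; cohorts sold
    before a sales ban persist until they retire.  If the ZEV sales
    share is 1 from period T onward, ICE stock is exactly zero from
    period T + lifetime.

    ``initial_stock`` columns: vehicle_class, technology,
    vintage_period, count (the stock on the road in 2020).

    Returns a tidy DataFrame ``vehicle_class, technology,
    vintage_period, period, count``.
    """
    if lifetime < 1:
        raise ValueError("lifetime must be >= 1 period")
    for v in sales_per_period.values():
        if v < 0:
            raise ValueError("sales must be nonnegative")
    cohorts: dict[tuple, float] = {}
    for _, r in initial_stock.iterrows():
        if r["count"] < 0:
            raise ValueError("initial stock counts must be nonnegative")
        key = (r["vehicle_class"], r["technology"], int(r["vintage_period"]))
        cohorts[key] = cohorts.get(key, 0.0) + float(r["count"])
    rows = []
    for period in PERIODS:
        # New sales in this period (2020 cohorts come from initial_stock).
        if period > 2020:
            for cls, sales in sales_per_period.items():
                zev = schedule.zev_sales_share.get((cls, period), 0.0)
                cohorts[(cls, "zev", period)] = cohorts.get((cls, "zev", period), 0.0) + sales * zev
                cohorts[(cls, "ice", period)] = cohorts.get((cls, "ice", period), 0.0) + sales * (1.0 - zev)
        for (cls, tech, vintage), count in sorted(cohorts.items()):
            if vintage <= period <= vintage + 5 * lifetime:
                rows.append(
                    {
                        "vehicle_class": cls,
                        "technology": tech,
                        "vintage_period": vintage,
                        "period": period,
                        "count": count,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regional emissions (energy-system-model stand-in)
# ---------------------------------------------------------------------------

@dataclass
class RegionalEmissions:
    """Regional emission trajectories plus the emission factors they
    were computed with.

    ``df`` columns: region_id, sector (egu|onroad), technology,
    pollutant, period, tons (short tons / yr).
    ``emission_factor`` columns: sector, technology, pollutant, factor
    (tons/MWh for egu technologies, tons/mile for on-road).
    ``egu_increment`` columns (possibly empty): region_id, pollutant,
    period, tons — the extra EGU emissions induced by vehicle
    electrification, to be sited by grow-in-place rather than by the
    frozen 2020 unit shares.
    """

    df: pd.DataFrame
    emission_factor: pd.DataFrame
    egu_increment: pd.DataFrame


# Default emission factors.  EGU: short tons per MWh of fossil
# generation; on-road ICE: short tons per vehicle-mile.
DEFAULT_EGU_EF = {
    ("coal", "NOx"): 1.5e-3,
    ("coal", "SO2"): 2.5e-3,
    ("coal", "PM2.5"): 2.0e-4,
    ("gas", "NOx"): 6.0e-4,
    ("gas", "SO2"): 5.0e-6,
    ("gas", "PM2.5"): 4.0e-5,
}
DEFAULT_ONROAD_EF = {
    ("ldv", "NOx"): 6.0e-7,
    ("ldv", "SO2"): 5.0e-9,
    ("ldv", "PM2.5"): 1.0e-8,
    ("mhdv", "NOx"): 5.0e-6,
    ("mhdv", "SO2"): 2.0e-8,
    ("mhdv", "PM2.5"): 1.5e-7,
}


@dataclass(frozen=True)
class ScenarioResponse:
    """Config knobs for the stylized scenario responses."""

    current_policy_decline: float = 0.02  # 1/yr exponential decline (IRA-like)
    carbon_tax_elasticity: float = 0.035  # per $/t CO2
    carbon_tax_floor: float = 0.08  # fraction of 2020 emissions
    ev_demand_increment: float = 0.35  # extra EGU output at full fleet electrification
    onroad_tax_elasticity: float = 0.010  # per $/t CO2 (milder than EGU)


def _egu_scale(schedule: PolicySchedule, period: int, resp: ScenarioResponse) -> float:
    """Fraction of 2020 fossil EGU emissions remaining in ``period``."""
    cp = float(np.exp(-resp.current_policy_decline * (period - 2020)))
    if schedule.name in ("current_policy", "ice_ban"):
        return cp
    if schedule.name in ("ces", "ice_ban_ces"):
        clean = schedule.ces_clean_fraction.get(period, 0.0)
        return min(cp, 1.0 - clean)
    if schedule.name == "carbon_tax":
        tax = schedule.carbon_tax.get(period, 0.0)
        return min(cp, max(resp.carbon_tax_floor, float(np.exp(-resp.carbon_tax_elasticity * tax))))
    if schedule.name == "net_zero":
        return min(cp, schedule.netzero_cap_fraction.get(period, 1.0))
    raise ValueError(f"unknown scenario name {schedule.name!r}")


def _onroad_scale(schedule: PolicySchedule, period: int, resp: ScenarioResponse) -> float:
    """Policy multiplier on ICE on-road emissions beyond fleet turnover."""
    if schedule.name == "net_zero":
        return schedule.netzero_cap_fraction.get(period, 1.0)
    if schedule.name == "carbon_tax":
        tax = schedule.carbon_tax.get(period, 0.0)
        return float(np.exp(-resp.onroad_tax_elasticity * tax))
    return 1.0


def zev_fleet_share(fleet: pd.DataFrame, period: int) -> float:
    """Share of the whole on-road stock that is zero-emission."""
    s = fleet[fleet["period"] == period]
    total = s["count"].sum()
    if total == 0:
        return 0.0
    return s.loc[s["technology"] == "zev", "count"].sum() / total


def ice_fleet_fraction(fleet: pd.DataFrame, vehicle_class: str, period: int) -> float:
    """ICE fraction of the stock in one vehicle class and period."""
    s = fleet[(fleet["period"] == period) & (fleet["vehicle_class"] == vehicle_class)]
    total = s["count"].sum()
    if total == 0:
        return 0.0
    return s.loc[s["technology"] == "ice", "count"].sum() / total


def gen_regional_emissions(
    schedule: PolicySchedule,
    fleet: pd.DataFrame,
    egu_fleet: pd.DataFrame,
    vmt: VMTSurrogate,
    counties: pd.DataFrame,
    seed: int,
    response: ScenarioResponse | None = None,
) -> RegionalEmissions:
    """Build regional emission trajectories for one policy scenario.

    EGU emissions start from 2020 fossil generation times the default
    emission factors and are scaled per period by the scenario response
    (CES: 1 - clean fraction; carbon tax: exponential decay with a
    floor; net-zero: the linear cap; current policy: a gentle
    exponential decline).  ICE-ban scenarios add an
    electricity-demand increment proportional to the electrified fleet
    share, reported separately so it can be sited by grow-in-place.
    On-road emissions are regional ICE VMT times emission factors,
    scaled by fleet turnover and any economy-wide policy.
    """
    if schedule.name not in SCENARIOS:
        raise ValueError(f"unknown scenario name {schedule.name!r}")
    resp = response or ScenarioResponse()
    county_region = counties.set_index("county_id")["region_id"]
    regions = sorted(counties["region_id"].unique())

    # 2020 EGU fossil emissions per region x fuel.
    existing = egu_fleet[egu_fleet["status"] == "existing"].copy()
    existing["region_id"] = existing["county_id"].map(county_region)
    gen_by = existing.groupby(["region_id", "fuel"])["gen_2020_mwh"].sum()

    rows = []
    inc_rows = []
    electrified = schedule.name in ("ice_ban", "ice_ban_ces")
    for period in PERIODS:
        scale = _egu_scale(schedule, period, resp)
        ev_extra = resp.ev_demand_increment * zev_fleet_share(fleet, period)
        for (region, fuel), gen in gen_by.items():
            for pol in POLLUTANTS:
                base = gen * DEFAULT_EGU_EF[(fuel, pol)]
                rows.append(
                    {
                        "region_id": region,
                        "sector": "egu",
                        "technology": fuel,
                        "pollutant": pol,
                        "period": period,
                        "tons": base * scale,
                    }
                )
                if electrified and fuel == "gas" and ev_extra > 0:
                    # EV charging demand met by (policy-scaled) gas
                    # capacity sited via grow-in-place.
                    inc_rows.append(
                        {
                            "region_id": region,
                            "pollutant": pol,
                            "period": period,
                            "tons": base * scale * ev_extra,
                        }
                    )

    # On-road: regional VMT from the 2023 surrogate pattern.
    v = vmt.vmt[vmt.vmt["surrogate_year"] == 2023].copy()
    v["region_id"] = v["county_id"].map(county_region)
    vmt_by = v.groupby(["region_id", "vehicle_type"])["vmt"].sum()
    for period in PERIODS:
        oscale = _onroad_scale(schedule, period, resp)
        for (region, vt), miles in vmt_by.items():
            ice_frac = ice_fleet_fraction(fleet, vt, period)
            for pol in POLLUTANTS:
                rows.append(
                    {
                        "region_id": region,
                        "sector": "onroad",
                        "technology": vt,
                        "pollutant": pol,
                        "period": period,
                        "tons": miles * ice_frac * DEFAULT_ONROAD_EF[(vt, pol)] * oscale,
                    }
                )

    ef_rows = [
        {"sector": "egu", "technology": t, "pollutant": p, "factor": f}
        for (t, p), f in DEFAULT_EGU_EF.items()
    ] + [
        {"sector": "onroad", "technology": t, "pollutant": p, "factor": f}
        for (t, p), f in DEFAULT_ONROAD_EF.items()
    ]
    inc = pd.DataFrame(inc_rows, columns=["region_id", "pollutant", "period", "tons"])
    return RegionalEmissions(
        df=pd.DataFrame(rows), emission_factor=pd.DataFrame(ef_rows), egu_increment=inc
    )


def default_initial_stock(n_per_class: float = 1e6) -> pd.DataFrame:
    """All-ICE 2020 starting stock, one vintage-2020 cohort per class."""
    return pd.DataFrame(
        [
            {"vehicle_class": c, "technology": "ice", "vintage_period": 2020, "count": n_per_class}
            for c in VEHICLE_CLASSES
        ]
    )
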