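"""Downscale regional emissions to counties.

Two allocation paths, both exactly mass-conserving:

* **EGU**: each cluster's regional emissions are split across its
  units in proportion to each unit's share of 2020 cluster generation
  (frozen over time), then summed to counties.  New capacity (e.g. the
  electricity-demand increment of a vehicle-electrification scenario)
  is sited by a grow-in-place heuristic: planned sites first, then
  retired sites, then existing same-fuel capacity.
* **On-road**: regional vehicle-miles travelled are shared out to
  counties by a VMT spatial surrogate (surrogate year keyed to the
  model period, with national scaling factors after 2032), then
  converted to emissions by technology-specific factors.
"""

from __future__ import annotations

import pandas as pd

from .synth import PERIODS, POLLUTANTS, RegionalEmissions, VMTSurrogate

HEIGHT_BINS = ["ground", "low", "medium", "tall"]


def unit_generation_shares(fleet: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster unit generation shares from the 2020 fleet.

    share(u) = gen_2020(u) / sum of gen_2020 over the unit's cluster.
    A cluster whose 2020 generation is zero gets uniform shares, which
    preserves mass conservation.  Shares are computed once from the
    2020 fleet and reused for every period.

    Only ``existing`` units enter; planned and retired-site records
    have zero generation by construction and are siting candidates,
    not dispatch units.
    """
    existing = fleet[fleet["status"] == "existing"]
    if existing.empty:
        raise ValueError("fleet has no existing units")
    out = []
    for cluster, grp in existing.groupby("cluster_id"):
        total = grp["gen_2020_mwh"].sum()
        if total > 0:
            shares = grp["gen_2020_mwh"] / total
        else:
            shares = pd.Series(1.0 / len(grp), index=grp.index)
        for (_, row), s in zip(grp.iterrows(), shares):
            out.append({"cluster_id": cluster, "unit_id": row["unit_id"], "share": float(s)})
    df = pd.DataFrame(out)
    sums = df.groupby("cluster_id")["share"].sum()
    assert (abs(sums - 1.0) < 1e-9).all()
    return df


def grow_in_place_allocate(
    new_capacity: pd.DataFrame,
    fleet: pd.DataFrame,
    counties: pd.DataFrame,
    tier_order: tuple[str, ...] = ("planned", "retired_site", "existing"),
) -> pd.DataFrame:
    """Site new capacity at planned, retired, then existing locations.

    ``new_capacity`` columns: region_id, fuel, mw.  Within each
    region x fuel, capacity fills the tiers in ``tier_order``:
    allocation within a tier is proportional to that tier's candidate
    capacity, a tier absorbs at most its own capacity (except the last
    tier, which takes any remainder proportionally), and the allocated
    total equals the requested total exactly.

    Planned and retired tiers accept any fuel's demand (a site is a
    site); the existing tier is restricted to same-fuel units.

    Returns site-level additions: unit_id, county_id, fuel, added_mw.
    """
    county_region = counties.set_index("county_id")["region_id"]
    f = fleet.copy()
    f["region_id"] = f["county_id"].map(county_region)
    out = []
    for _, req in new_capacity.iterrows():
        region, fuel, mw = req["region_id"], req["fuel"], float(req["mw"])
        if mw < 0:
            raise ValueError("new capacity must be nonnegative")
        if mw == 0:
            continue
        remaining = mw
        in_region = f[f["region_id"] == region]
        any_candidates = False
        for i, tier in enumerate(tier_order):
            cand = in_region[in_region["status"] == tier]
            if tier == "existing":
                cand = cand[cand["fuel"] == fuel]
            cap = cand["capacity_mw"].sum()
            if cand.empty or cap <= 0:
                continue
            any_candidates = True
            last_tier = i == len(tier_order) - 1
            take = remaining if last_tier else min(remaining, cap)
            for _, site in cand.iterrows():
                out.append(
                    {
                        "unit_id": site["unit_id"],
                        "county_id": site["county_id"],
                        "fuel": fuel,
                        "added_mw": take * site["capacity_mw"] / cap,
                    }
                )
            remaining -= take
            if remaining <= 1e-12:
                break
        if remaining > 1e-9 or not any_candidates:
            raise ValueError(
                f"region {region}: no siting candidates for {remaining:.3f} MW of {fuel}"
            )
    cols = ["unit_id", "county_id", "fuel", "added_mw"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out, columns=cols).groupby(cols[:3], as_index=False)["added_mw"].sum()


def egu_emissions_to_counties(
    regional: RegionalEmissions,
    shares: pd.DataFrame,
    fleet: pd.DataFrame,
    counties: pd.DataFrame,
    additions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Allocate regional EGU emissions to counties.

    Regional rows are keyed by region x fuel technology.  Each
    region-fuel total is first split across that region's clusters in
    proportion to cluster 2020 generation in the fuel, then across the
    cluster's units by the frozen 2020 shares, then summed by county
    and height bin.  The electrification increment (if present) is
    spread over grow-in-place addition sites in proportion to added
    capacity; each addition site behaves as a one-unit cluster.

    Returns ``county_id, sector, pollutant, height_bin, period, tons``
    whose per-region sums equal the regional totals to 1e-9 relative.
    """
    county_region = counties.set_index("county_id")["region_id"]
    existing = fleet[fleet["status"] == "existing"].copy()
    existing["region_id"] = existing["county_id"].map(county_region)
    share_map = shares.set_index("unit_id")["share"]
    cluster_of = existing.set_index("unit_id")["cluster_id"]
    missing = set(cluster_of.unique()) - set(shares["cluster_id"].unique())
    if missing:
        raise KeyError(f"share table missing clusters: {sorted(missing)}")

    # unit weight within (region, fuel) = cluster weight x unit share
    cluster_gen = existing.groupby(["region_id", "fuel", "cluster_id"])["gen_2020_mwh"].sum()
    rf_gen = cluster_gen.groupby(level=[0, 1]).sum()

    unit_rows = []
    for _, u in existing.iterrows():
        rf = (u["region_id"], u["fuel"])
        denom = rf_gen.loc[rf]
        if denom > 0:
            cw = cluster_gen.loc[(u["region_id"], u["fuel"], u["cluster_id"])] / denom
        else:
            n_clusters = len(cluster_gen.loc[rf])
            cw = 1.0 / n_clusters
        unit_rows.append(
            {
                "region_id": u["region_id"],
                "fuel": u["fuel"],
                "county_id": u["county_id"],
                "height_bin": u["height_bin"],
                "weight": cw * share_map[u["unit_id"]],
            }
        )
    weights = pd.DataFrame(unit_rows)

    egu = regional.df[regional.df["sector"] == "egu"]
    merged = egu.merge(
        weights,
        left_on=["region_id", "technology"],
        right_on=["region_id", "fuel"],
        how="left",
    )
    has_mass = merged["tons"] > 0
    if merged.loc[has_mass, "weight"].isna().any():
        bad = merged.loc[has_mass & merged["weight"].isna(), ["region_id", "technology"]]
        raise KeyError(f"no units for region-fuel combinations: {bad.drop_duplicates().to_dict('records')}")
    merged = merged.dropna(subset=["weight"])
    merged["county_tons"] = merged["tons"] * merged["weight"]
    out = (
        merged.groupby(["county_id", "pollutant", "height_bin", "period"], as_index=False)[
            "county_tons"
        ]
        .sum()
        .rename(columns={"county_tons": "tons"})
    )
    out.insert(1, "sector", "egu")

    # Electrification increment over grow-in-place sites.
    inc = regional.egu_increment
    if additions is not None and not additions.empty and not inc.empty:
        add = additions.copy()
        add["region_id"] = add["county_id"].map(county_region)
        add_w = add.groupby(["region_id", "county_id"], as_index=False)["added_mw"].sum()
        region_mw = add_w.groupby("region_id")["added_mw"].transform("sum")
        add_w["weight"] = add_w["added_mw"] / region_mw
        m = inc.merge(add_w[["region_id", "county_id", "weight"]], on="region_id", how="left")
        if m.loc[m["tons"] > 0, "weight"].isna().any():
            bad = sorted(m.loc[(m["tons"] > 0) & m["weight"].isna(), "region_id"].unique())
            raise ValueError(f"electrification increment in regions without siting: {bad}")
        m = m.dropna(subset=["weight"])
        m["tons"] = m["tons"] * m["weight"]
        m["sector"] = "egu"
        m["height_bin"] = "medium"  # new thermal capacity: point-source bin
        out = pd.concat(
            [out, m[["county_id", "sector", "pollutant", "height_bin", "period", "tons"]]],
            ignore_index=True,
        )
        out = out.groupby(
            ["county_id", "sector", "pollutant", "height_bin", "period"], as_index=False
        )["tons"].sum()
    elif not inc.empty and (inc["tons"] > 0).any():
        raise ValueError("regional emissions carry an electrification increment but no additions were supplied")
    return out


_PERIOD_TO_SURROGATE = {2020: 2023, 2025: 2026, 2030: 2032}


def downscale_vmt(
    regional_vmt: pd.DataFrame,
    surrogate: VMTSurrogate,
    counties: pd.DataFrame,
    period: int,
) -> pd.DataFrame:
    """Share regional VMT out to counties via the spatial surrogate.

    The surrogate year is keyed to the model period (2020-2024 -> 2023,
    2025-2029 -> 2026, 2030-2034 -> 2032); periods from 2035 use the
    2032 surrogate times the national scaling factor for the vehicle
    type.  County VMT is VMT(type, region) x S(type, county) /
    sum over the region's counties of S, so county values sum to the
    regional totals exactly.  A uniform scaling factor cancels in the
    shares.

    ``regional_vmt`` columns: region_id, vehicle_type, vmt.
    Returns ``county_id, vehicle_type, period, vmt``.
    """
    if period in _PERIOD_TO_SURROGATE:
        sy = _PERIOD_TO_SURROGATE[period]
        scale = None
    elif period >= 2035:
        sy = 2032
        scale = surrogate.national_scale[surrogate.national_scale["period"] == period]
        scale = scale.set_index("vehicle_type")["factor"]
    else:
        raise ValueError(f"period {period} outside the modelled horizon")

    s = surrogate.vmt[surrogate.vmt["surrogate_year"] == sy].copy()
    county_region = counties.set_index("county_id")["region_id"]
    s["region_id"] = s["county_id"].map(county_region)
    if scale is not None:
        s["vmt"] = s["vmt"] * s["vehicle_type"].map(scale)
    denom = s.groupby(["region_id", "vehicle_type"])["vmt"].transform("sum")
    s["share"] = s["vmt"] / denom.where(denom > 0)

    m = regional_vmt.merge(
        s[["region_id", "vehicle_type", "county_id", "share"]],
        on=["region_id", "vehicle_type"],
        how="left",
    )
    bad = m[(m["vmt"] > 0) & m["share"].isna()]
    if not bad.empty:
        raise ValueError(
            "zero surrogate total for regions with nonzero VMT: "
            f"{sorted(bad['region_id'].unique())}"
        )
    m = m.dropna(subset=["share"])
    m["county_vmt"] = m["vmt"] * m["share"]
    out = m[["county_id", "vehicle_type", "county_vmt"]].rename(columns={"county_vmt": "vmt"})
    out["period"] = period
    return out.reset_index(drop=True)


def vmt_to_emissions(county_vmt: pd.DataFrame, emission_factor: pd.DataFrame) -> pd.DataFrame:
    """Convert county VMT to emissions at ground level.

    ``emission_factor`` columns: technology, pollutant, factor
    (short tons per mile); zero-emission technologies simply carry
    zero factors.  Raises if a technology present in the VMT table has
    no factor for some pollutant.
    """
    if (emission_factor["factor"] < 0).any():
        raise ValueError("emission factors must be nonnegative")
    techs = set(county_vmt["vehicle_type"].unique())
    have = emission_factor.groupby("technology")["pollutant"].nunique()
    missing = [t for t in techs if t not in have.index or have[t] < len(POLLUTANTS)]
    if missing:
        raise KeyError(f"missing emission factors for technologies: {sorted(missing)}")
    m = county_vmt.merge(
        emission_factor.rename(columns={"technology": "vehicle_type"}),
        on="vehicle_type",
    )
    m["tons"] = m["vmt"] * m["factor"]
    out = (
        m.groupby(["county_id", "pollutant", "period"], as_index=False)["tons"].sum()
    )
    out.insert(1, "sector", "onroad")
    out["height_bin"] = "ground"
    return out[["county_id", "sector", "pollutant", "height_bin", "period", "tons"]]


def downscale_scenario(
    regional: RegionalEmissions,
    fleet: pd.DataFrame,
    surrogate: VMTSurrogate,
    counties: pd.DataFrame,
    shares: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run both downscaling paths for every period of one scenario.

    On-road regional emissions are allocated with the VMT surrogate
    shares for the period; EGU emissions with the frozen unit shares
    plus grow-in-place siting of any electrification increment.
    Returns the combined county emission table.
    """
    if shares is None:
        shares = unit_generation_shares(fleet)
    additions = None
    if not regional.egu_increment.empty and (regional.egu_increment["tons"] > 0).any():
        # Size new gas capacity per region from the peak increment; the
        # exact MW level does not matter for allocation, only the site mix.
        peak = regional.egu_increment.groupby("region_id")["tons"].max()
        new_cap = pd.DataFrame(
            {"region_id": peak.index, "fuel": "gas", "mw": 100.0 * peak / peak.max()}
        )
        additions = grow_in_place_allocate(new_cap, fleet, counties)
    egu = egu_emissions_to_counties(regional, shares, fleet, counties, additions)

    onroad_parts = []
    onroad = regional.df[regional.df["sector"] == "onroad"]
    ef = regional.emission_factor[regional.emission_factor["sector"] == "onroad"]
    for period in PERIODS:
        rows = onroad[onroad["period"] == period]
        # Convert emissions back to an implied regional VMT per
        # technology so the surrogate shares apply uniformly across
        # pollutants, then share out and re-apply factors.
        nox = rows[rows["pollutant"] == "NOx"]
        ef_nox = ef[ef["pollutant"] == "NOx"].set_index("technology")["factor"]
        reg_vmt = nox.assign(vmt=nox["tons"] / nox["technology"].map(ef_nox))[
            ["region_id", "technology", "vmt"]
        ].rename(columns={"technology": "vehicle_type"})
        cvmt = downscale_vmt(reg_vmt, surrogate, counties, period)
        onroad_parts.append(
            vmt_to_emissions(cvmt, ef.rename(columns={"sector": "_s"}).drop(columns="_s"))
        )
    out = pd.concat([egu] + onroad_parts, ignore_index=True)
    return out[out["tons"].notna()].reset_index(drop=True)
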