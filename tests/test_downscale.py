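"""Downscaling: unit shares, grow-in-place siting, and the two
mass-conserving county allocation paths."""

import numpy as np
import pandas as pd
import pytest
from aqequity.downscale import (
    downscale_scenario,
    downscale_vmt,
    egu_emissions_to_counties,
    grow_in_place_allocate,
    unit_generation_shares,
    vmt_to_emissions,
)
from aqequity.synth import (
    RegionalEmissions,
    VMTSurrogate,
    default_initial_stock,
    default_schedule,
    fleet_turnover,
    gen_counties,
    gen_egu_fleet,
    gen_population,
    gen_regional_emissions,
    gen_vmt_surrogate,
    DemographicTrajectory,
)


def make_fleet(rows):
    defaults = {
        "plant_id": "P0",
        "fuel": "gas",
        "capacity_mw": 100.0,
        "gen_2020_mwh": 0.0,
        "status": "existing",
        "height_bin": "medium",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestUnitShares:
    def test_proportional_split(self):
        fleet = make_fleet(
            [
                {"unit_id": "A", "cluster_id": "C1", "county_id": "x", "gen_2020_mwh": 60.0},
                {"unit_id": "B", "cluster_id": "C1", "county_id": "y", "gen_2020_mwh": 40.0},
            ]
        )
        s = unit_generation_shares(fleet).set_index("unit_id")["share"]
        assert s["A"] == pytest.approx(0.6)
        assert s["B"] == pytest.approx(0.4)

    def test_single_unit_cluster(self):
        fleet = make_fleet(
            [{"unit_id": "A", "cluster_id": "C1", "county_id": "x", "gen_2020_mwh": 5.0}]
        )
        s = unit_generation_shares(fleet)
        assert s["share"].tolist() == [1.0]

    def test_zero_generation_cluster_uniform(self):
        fleet = make_fleet(
            [
                {"unit_id": "A", "cluster_id": "C1", "county_id": "x"},
                {"unit_id": "B", "cluster_id": "C1", "county_id": "y"},
            ]
        )
        s = unit_generation_shares(fleet).set_index("unit_id")["share"]
        assert s["A"] == pytest.approx(0.5)
        assert s["B"] == pytest.approx(0.5)

    def test_no_existing_units_rejected(self):
        fleet = make_fleet(
            [{"unit_id": "A", "cluster_id": "C1", "county_id": "x", "status": "planned"}]
        )
        with pytest.raises(ValueError):
            unit_generation_shares(fleet)


@pytest.fixture()
def siting_counties():
    return pd.DataFrame(
        {
            "county_id": ["a", "b", "c", "d", "e"],
            "region_id": [1, 1, 1, 1, 1],
            "cx": 0.0, "cy": 0.0, "area": 1.0, "pw_x": 0.0, "pw_y": 0.0,
        }
    )


class TestGrowInPlace:
    def test_planned_then_retired_tiers(self, siting_counties):
        fleet = make_fleet(
            [
                {"unit_id": "P1", "cluster_id": "p", "county_id": "a", "status": "planned", "capacity_mw": 60.0},
                {"unit_id": "R1", "cluster_id": "r", "county_id": "b", "status": "retired_site", "capacity_mw": 80.0},
            ]
        )
        req = pd.DataFrame([{"region_id": 1, "fuel": "gas", "mw": 100.0}])
        add = grow_in_place_allocate(req, fleet, siting_counties).set_index("unit_id")["added_mw"]
        assert add["P1"] == pytest.approx(60.0)
        assert add["R1"] == pytest.approx(40.0)

    def test_zero_request_no_additions(self, siting_counties):
        fleet = make_fleet(
            [{"unit_id": "P1", "cluster_id": "p", "county_id": "a", "status": "planned"}]
        )
        req = pd.DataFrame([{"region_id": 1, "fuel": "gas", "mw": 0.0}])
        add = grow_in_place_allocate(req, fleet, siting_counties)
        assert add.empty

    def test_three_tier_hand_allocation(self, siting_counties):
        # 300 MW: planned P1 60; retired R1 50 + R2 150 (tier filled
        # proportionally, 200 total); remaining 40 over existing gas
        # capacity E1 100 / E2 300 -> 10 / 30.
        fleet = make_fleet(
            [
                {"unit_id": "P1", "cluster_id": "p", "county_id": "a", "status": "planned", "capacity_mw": 60.0},
                {"unit_id": "R1", "cluster_id": "r", "county_id": "b", "status": "retired_site", "capacity_mw": 50.0},
                {"unit_id": "R2", "cluster_id": "r", "county_id": "c", "status": "retired_site", "capacity_mw": 150.0},
                {"unit_id": "E1", "cluster_id": "e", "county_id": "d", "capacity_mw": 100.0, "gen_2020_mwh": 1.0},
                {"unit_id": "E2", "cluster_id": "e", "county_id": "e", "capacity_mw": 300.0, "gen_2020_mwh": 1.0},
            ]
        )
        req = pd.DataFrame([{"region_id": 1, "fuel": "gas", "mw": 300.0}])
        add = grow_in_place_allocate(req, fleet, siting_counties).set_index("unit_id")["added_mw"]
        assert add["P1"] == pytest.approx(60.0)
        assert add["R1"] == pytest.approx(50.0)
        assert add["R2"] == pytest.approx(150.0)
        assert add["E1"] == pytest.approx(10.0)
        assert add["E2"] == pytest.approx(30.0)
        assert add.sum() == pytest.approx(300.0)

    def test_error_names_region_without_candidates(self, siting_counties):
        fleet = make_fleet(
            [{"unit_id": "E1", "cluster_id": "e", "county_id": "a", "fuel": "coal", "gen_2020_mwh": 1.0}]
        )
        req = pd.DataFrame([{"region_id": 1, "fuel": "gas", "mw": 10.0}])
        with pytest.raises(ValueError, match="region 1"):
            grow_in_place_allocate(req, fleet, siting_counties)


def regional_frame(rows):
    return RegionalEmissions(
        df=pd.DataFrame(rows),
        emission_factor=pd.DataFrame(columns=["sector", "technology", "pollutant", "factor"]),
        egu_increment=pd.DataFrame(columns=["region_id", "pollutant", "period", "tons"]),
    )


class TestEguToCounties:
    def test_two_unit_split(self, siting_counties):
        fleet = make_fleet(
            [
                {"unit_id": "A", "cluster_id": "C1", "county_id": "a", "gen_2020_mwh": 60.0},
                {"unit_id": "B", "cluster_id": "C1", "county_id": "b", "gen_2020_mwh": 40.0},
            ]
        )
        shares = unit_generation_shares(fleet)
        regional = regional_frame(
            [{"region_id": 1, "sector": "egu", "technology": "gas", "pollutant": "SO2", "period": 2020, "tons": 100.0}]
        )
        out = egu_emissions_to_counties(regional, shares, fleet, siting_counties)
        by = out.set_index("county_id")["tons"]
        assert by["a"] == pytest.approx(60.0)
        assert by["b"] == pytest.approx(40.0)

    def test_same_county_aggregates(self, siting_counties):
        fleet = make_fleet(
            [
                {"unit_id": "A", "cluster_id": "C1", "county_id": "a", "gen_2020_mwh": 60.0},
                {"unit_id": "B", "cluster_id": "C1", "county_id": "a", "gen_2020_mwh": 40.0},
            ]
        )
        shares = unit_generation_shares(fleet)
        regional = regional_frame(
            [{"region_id": 1, "sector": "egu", "technology": "gas", "pollutant": "SO2", "period": 2020, "tons": 100.0}]
        )
        out = egu_emissions_to_counties(regional, shares, fleet, siting_counties)
        assert len(out) == 1
        assert out["tons"].iloc[0] == pytest.approx(100.0)

    def test_randomized_fleet_conserves_mass(self, counties20, population20):
        fleet = gen_egu_fleet(counties20, 7, 3, seed=31)
        vmt = gen_vmt_surrogate(counties20, population20, seed=32)
        sched = default_schedule("current_policy")
        stock = fleet_turnover(sched, default_initial_stock(1e5), 3, {"ldv": 2e4, "mhdv": 3e3})
        regional = gen_regional_emissions(sched, stock, fleet, vmt, counties20, seed=33)
        shares = unit_generation_shares(fleet)
        out = egu_emissions_to_counties(regional, shares, fleet, counties20)
        region = counties20.set_index("county_id")["region_id"]
        got = (
            out.assign(region_id=out["county_id"].map(region))
            .groupby(["region_id", "pollutant", "period"])["tons"].sum()
        )
        want = (
            regional.df[regional.df["sector"] == "egu"]
            .groupby(["region_id", "pollutant", "period"])["tons"].sum()
        )
        want = want[want > 0]
        rel = (got.reindex(want.index) - want).abs() / want
        assert rel.max() < 1e-9

    def test_missing_cluster_share_rejected(self, siting_counties):
        fleet = make_fleet(
            [{"unit_id": "A", "cluster_id": "C1", "county_id": "a", "gen_2020_mwh": 10.0}]
        )
        shares = pd.DataFrame([{"cluster_id": "OTHER", "unit_id": "Z", "share": 1.0}])
        regional = regional_frame(
            [{"region_id": 1, "sector": "egu", "technology": "gas", "pollutant": "SO2", "period": 2020, "tons": 1.0}]
        )
        with pytest.raises(KeyError):
            egu_emissions_to_counties(regional, shares, fleet, siting_counties)


def surrogate_for(counties, values_by_type, scale_rows=None):
    rows = []
    for vt, vals in values_by_type.items():
        for year in (2023, 2026, 2032):
            for cid, v in zip(counties["county_id"], vals):
                rows.append(
                    {"county_id": cid, "vehicle_type": vt, "surrogate_year": year, "vmt": v}
                )
    scale = pd.DataFrame(
        scale_rows
        or [
            {"vehicle_type": vt, "period": p, "factor": 1.0}
            for vt in values_by_type
            for p in (2035, 2040, 2045, 2050)
        ]
    )
    return VMTSurrogate(vmt=pd.DataFrame(rows), national_scale=scale)


class TestDownscaleVmt:
    def test_share_split(self, siting_counties):
        c = siting_counties.iloc[:2]
        surr = surrogate_for(c, {"ldv": [30.0, 70.0]})
        reg = pd.DataFrame([{"region_id": 1, "vehicle_type": "ldv", "vmt": 100.0}])
        out = downscale_vmt(reg, surr, c, 2020).set_index("county_id")["vmt"]
        assert out["a"] == pytest.approx(30.0)
        assert out["b"] == pytest.approx(70.0)

    def test_hand_share_arithmetic(self, siting_counties):
        c = siting_counties.iloc[:3]
        surr = surrogate_for(c, {"ldv": [10.0, 30.0, 60.0]})
        reg = pd.DataFrame([{"region_id": 1, "vehicle_type": "ldv", "vmt": 500.0}])
        out = downscale_vmt(reg, surr, c, 2030).set_index("county_id")["vmt"]
        assert out.tolist() == pytest.approx([50.0, 150.0, 300.0])

    def test_uniform_national_scale_cancels(self, siting_counties):
        c = siting_counties.iloc[:3]
        surr_1 = surrogate_for(c, {"ldv": [10.0, 30.0, 60.0]})
        scale_11 = [
            {"vehicle_type": "ldv", "period": p, "factor": 1.1} for p in (2035, 2040, 2045, 2050)
        ]
        surr_11 = surrogate_for(c, {"ldv": [10.0, 30.0, 60.0]}, scale_rows=scale_11)
        reg = pd.DataFrame([{"region_id": 1, "vehicle_type": "ldv", "vmt": 500.0}])
        a = downscale_vmt(reg, surr_1, c, 2040).set_index("county_id")["vmt"]
        b = downscale_vmt(reg, surr_11, c, 2040).set_index("county_id")["vmt"]
        assert np.allclose(a, b, rtol=1e-12)

    def test_zero_surrogate_with_vmt_rejected(self, siting_counties):
        c = siting_counties.iloc[:2]
        surr = surrogate_for(c, {"ldv": [0.0, 0.0]})
        reg = pd.DataFrame([{"region_id": 1, "vehicle_type": "ldv", "vmt": 10.0}])
        with pytest.raises(ValueError):
            downscale_vmt(reg, surr, c, 2020)


class TestVmtToEmissions:
    def test_zero_factor_technology(self):
        cvmt = pd.DataFrame(
            [{"county_id": "a", "vehicle_type": "zev", "period": 2030, "vmt": 1e9}]
        )
        ef = pd.DataFrame(
            [
                {"technology": "zev", "pollutant": p, "factor": 0.0}
                for p in ("NOx", "SO2", "PM2.5")
            ]
        )
        out = vmt_to_emissions(cvmt, ef)
        assert (out["tons"] == 0).all()
        assert (out["height_bin"] == "ground").all()

    def test_arithmetic(self):
        cvmt = pd.DataFrame(
            [{"county_id": "a", "vehicle_type": "ldv", "period": 2030, "vmt": 1e6}]
        )
        ef = pd.DataFrame(
            [
                {"technology": "ldv", "pollutant": "NOx", "factor": 1e-5},
                {"technology": "ldv", "pollutant": "SO2", "factor": 0.0},
                {"technology": "ldv", "pollutant": "PM2.5", "factor": 0.0},
            ]
        )
        out = vmt_to_emissions(cvmt, ef)
        nox = out[out["pollutant"] == "NOx"]["tons"].iloc[0]
        assert nox == pytest.approx(10.0)

    def test_two_technology_sum(self):
        cvmt = pd.DataFrame(
            [
                {"county_id": "a", "vehicle_type": "ldv", "period": 2030, "vmt": 1e6},
                {"county_id": "a", "vehicle_type": "mhdv", "period": 2030, "vmt": 2e5},
            ]
        )
        ef = pd.DataFrame(
            [
                {"technology": "ldv", "pollutant": "NOx", "factor": 1e-5},
                {"technology": "ldv", "pollutant": "SO2", "factor": 0.0},
                {"technology": "ldv", "pollutant": "PM2.5", "factor": 0.0},
                {"technology": "mhdv", "pollutant": "NOx", "factor": 5e-5},
                {"technology": "mhdv", "pollutant": "SO2", "factor": 0.0},
                {"technology": "mhdv", "pollutant": "PM2.5", "factor": 0.0},
            ]
        )
        out = vmt_to_emissions(cvmt, ef)
        nox = out[out["pollutant"] == "NOx"]["tons"].iloc[0]
        assert nox == pytest.approx(1e6 * 1e-5 + 2e5 * 5e-5)

    def test_missing_factor_rejected(self):
        cvmt = pd.DataFrame(
            [{"county_id": "a", "vehicle_type": "bus", "period": 2030, "vmt": 1.0}]
        )
        ef = pd.DataFrame([{"technology": "ldv", "pollutant": "NOx", "factor": 1e-5}])
        with pytest.raises(KeyError):
            vmt_to_emissions(cvmt, ef)


@pytest.fixture(scope="module")
def scenario_out(counties20, population20):
    fleet = gen_egu_fleet(counties20, 7, 3, seed=41)
    vmt = gen_vmt_surrogate(counties20, population20, seed=42)
    sched = default_schedule("ice_ban")
    stock = fleet_turnover(sched, default_initial_stock(1e5), 3, {"ldv": 2e4, "mhdv": 3e3})
    regional = gen_regional_emissions(sched, stock, fleet, vmt, counties20, seed=43)
    county = downscale_scenario(regional, fleet, vmt, counties20)
    return regional, county, counties20


class TestScenarioDownscaling:
    def test_full_conservation_both_sectors(self, scenario_out):
        regional, county, counties = scenario_out
        region = counties.set_index("county_id")["region_id"]
        got = (
            county.assign(region_id=county["county_id"].map(region))
            .groupby(["region_id", "sector", "pollutant", "period"])["tons"].sum()
        )
        want = regional.df.groupby(["region_id", "sector", "pollutant", "period"])["tons"].sum()
        inc = regional.egu_increment.groupby(["region_id", "pollutant", "period"])["tons"].sum()
        for (r, p, t), v in inc.items():
            want[(r, "egu", p, t)] += v
        want = want[want > 0]
        rel = (got.reindex(want.index) - want).abs() / want
        assert rel.max() < 1e-9

    def test_transport_entries_at_ground(self, scenario_out):
        _, county, _ = scenario_out
        onroad = county[county["sector"] == "onroad"]
        assert (onroad["height_bin"] == "ground").all()

    def test_scaling_regional_total_scales_counties(self, counties20, population20):
        fleet = gen_egu_fleet(counties20, 5, 2, seed=51)
        shares = unit_generation_shares(fleet)
        region = counties20.set_index("county_id")["region_id"]
        existing = fleet[fleet["status"] == "existing"]
        combos = (
            existing.assign(region_id=existing["county_id"].map(region))[["region_id", "fuel"]]
            .drop_duplicates()
        )
        base_rows = [
            {"region_id": r, "sector": "egu", "technology": f, "pollutant": "SO2",
             "period": 2020, "tons": 100.0}
            for r, f in combos.itertuples(index=False)
        ]
        lam = 3.7
        out1 = egu_emissions_to_counties(regional_frame(base_rows), shares, fleet, counties20)
        scaled = [dict(r, tons=r["tons"] * lam) for r in base_rows]
        out2 = egu_emissions_to_counties(regional_frame(scaled), shares, fleet, counties20)
        merged = out1.merge(out2, on=["county_id", "pollutant", "height_bin", "period"])
        assert np.allclose(merged["tons_y"], lam * merged["tons_x"], rtol=1e-12)
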