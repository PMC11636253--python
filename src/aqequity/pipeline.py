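"""Scenario orchestration: generate -> downscale -> air quality ->
exposure equity -> health, across policy scenarios.

One root seed deterministically spawns per-module substreams, so each
generator is independently testable while the full pipeline remains
byte-reproducible.  Outputs are plain CSV/GeoJSON plus a JSON run
manifest (seed, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .airquality import ChemConfig, MetConfig, build_source_receptor_set, total_pm_field
from .downscale import downscale_scenario, unit_generation_shares
from .equity import exposure_summary, pw_exposure, weighted_quantile
from .health import (
    MortalityRates,
    RelativeRiskConfig,
    avoided_deaths,
    per_capita_deaths,
    scenario_deaths,
)
from .io import counties_to_geojson, write_csv
from .synth import (
    GROUPS,
    PERIODS,
    SCENARIOS,
    DemographicTrajectory,
    ScenarioResponse,
    default_initial_stock,
    default_schedule,
    fleet_turnover,
    gen_counties,
    gen_egu_fleet,
    gen_population,
    gen_regional_emissions,
    gen_vmt_surrogate,
)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable).

    The defaults define the standard synthetic study conditions: a
    9-region, 54-county domain on a 3000 km square, 30 M people in
    2020 growing 20% by 2050, a 27-cluster EGU fleet, and a
    three-period (15-year) vehicle lifetime.
    """

    seed: int = 42
    n_regions: int = 9
    counties_per_region: int = 6
    domain_size_km: float = 3000.0
    base_population: float = 30e6
    n_clusters: int = 27
    units_per_cluster: int = 3
    vehicle_lifetime_periods: int = 3
    sales_per_period: dict = field(default_factory=lambda: {"ldv": 200000.0, "mhdv": 30000.0})
    initial_stock_per_class: float = 1e6
    scenarios: list = field(default_factory=lambda: list(SCENARIOS))
    variants: list = field(default_factory=lambda: ["A", "B", "C"])
    calibration: float = 1.0
    quantile_method: str = "midpoint"
    trajectory: DemographicTrajectory = field(default_factory=DemographicTrajectory)
    met: MetConfig = field(default_factory=MetConfig)
    chem: ChemConfig = field(default_factory=ChemConfig)
    response: ScenarioResponse = field(default_factory=ScenarioResponse)
    outdir: str = "aqequity_out"

    def __post_init__(self):
        unknown = [s for s in self.scenarios if s not in SCENARIOS]
        if unknown:
            raise ValueError(f"unknown scenarios: {unknown}")
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "trajectory" in kwargs:
            t = kwargs["trajectory"]
            kwargs["trajectory"] = DemographicTrajectory(
                total_growth_2050=t.get("total_growth_2050", 0.20),
                group_share_anchors={
                    g: tuple(v) for g, v in t.get("group_share_anchors", {}).items()
                }
                or DemographicTrajectory().group_share_anchors,
            )
        for key, klass in (("met", MetConfig), ("chem", ChemConfig), ("response", ScenarioResponse)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        fields = {f.name: f for f in dataclasses.fields(cls)}
        bad = set(kwargs) - set(fields)
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}; valid keys are {sorted(fields)}")
        # YAML 1.1 reads unsigned exponents ("1.0e6") as strings; coerce
        # scalar fields to their declared types with a clear error.
        for name, val in list(kwargs.items()):
            target = fields[name].type
            try:
                if target == "int":
                    kwargs[name] = int(val)
                elif target == "float":
                    kwargs[name] = float(val)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config key {name!r} must be a {target}: got {val!r}") from exc
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(str(type(o)))

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _substreams(seed: int, n: int) -> list[int]:
    """Spawn n deterministic 31-bit child seeds from the root seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class Inputs:
    counties: pd.DataFrame
    population: pd.DataFrame
    egu_fleet: pd.DataFrame
    vmt_surrogate: object
    unit_shares: pd.DataFrame


def generate_inputs(config: RunConfig) -> Inputs:
    """Generate the scenario-independent synthetic inputs."""
    s_geo, s_pop, s_fleet, s_vmt, _ = _substreams(config.seed, 5)
    counties = gen_counties(
        config.n_regions, config.counties_per_region, config.domain_size_km, s_geo
    )
    population = gen_population(counties, config.trajectory, config.base_population, s_pop)
    egu_fleet = gen_egu_fleet(counties, config.n_clusters, config.units_per_cluster, s_fleet)
    vmt = gen_vmt_surrogate(counties, population, s_vmt)
    shares = unit_generation_shares(egu_fleet)
    return Inputs(counties, population, egu_fleet, vmt, shares)


def county_emissions_for(config: RunConfig, scenario: str, inputs: Inputs) -> pd.DataFrame:
    """Regional emission trajectories for a scenario, downscaled to
    counties (both EGU and on-road paths)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    *_, s_emis = _substreams(config.seed, 5)
    schedule = default_schedule(scenario)
    stock = fleet_turnover(
        schedule,
        default_initial_stock(config.initial_stock_per_class),
        config.vehicle_lifetime_periods,
        config.sales_per_period,
    )
    regional = gen_regional_emissions(
        schedule, stock, inputs.egu_fleet, inputs.vmt_surrogate, inputs.counties,
        s_emis, config.response,
    )
    county = downscale_scenario(
        regional, inputs.egu_fleet, inputs.vmt_surrogate, inputs.counties, inputs.unit_shares
    )
    return county


def baseline_inventory(config: RunConfig, inputs: Inputs) -> pd.DataFrame:
    """Reference-period inventory for the add-one-ton chemistry: the
    current-policy 2020 county emissions (the NEI-style baseline)."""
    cp = county_emissions_for(config, "current_policy", inputs)
    return cp[cp["period"] == 2020].drop(columns="period").assign(period=2020)


@dataclass
class ScenarioResult:
    scenario: str
    county_emissions: pd.DataFrame
    field: pd.DataFrame  # county_id, period, sector, conc
    exposure: pd.DataFrame
    deaths: pd.DataFrame


def run_scenario(config: RunConfig, scenario: str, inputs: Inputs | None = None,
                 sr=None) -> ScenarioResult:
    """Run one scenario end-to-end.

    The source-receptor set can be passed in to avoid rebuilding it
    per scenario (it depends only on the geography and the baseline
    inventory, not on the policy)."""
    inputs = inputs or generate_inputs(config)
    met = dataclasses.replace(config.met, calibration=config.calibration)
    if sr is None:
        baseline = baseline_inventory(config, inputs)
        sr = build_source_receptor_set(inputs.counties, baseline, met, config.chem)
    county = county_emissions_for(config, scenario, inputs)
    field = total_pm_field(county, sr, by_sector=True)
    exposure = exposure_summary(field, inputs.population)
    exposure.insert(0, "scenario", scenario)
    rates = MortalityRates()
    rrconf = RelativeRiskConfig()
    deaths = scenario_deaths(field, inputs.population, rates, rrconf, config.variants)
    deaths.insert(0, "scenario", scenario)
    return ScenarioResult(scenario, county, field, exposure, deaths)


def run_all(config: RunConfig) -> tuple[dict[str, ScenarioResult], Inputs]:
    """Run every configured scenario against a shared source-receptor
    set; returns the per-scenario results and the shared inputs."""
    inputs = generate_inputs(config)
    met = dataclasses.replace(config.met, calibration=config.calibration)
    baseline = baseline_inventory(config, inputs)
    sr = build_source_receptor_set(inputs.counties, baseline, met, config.chem)
    return {
        s: run_scenario(config, s, inputs, sr) for s in config.scenarios
    }, inputs


def compare_scenarios(results: dict, inputs: Inputs) -> dict[str, pd.DataFrame]:
    """Cross-scenario comparison tables.

    Produces the long exposure/disparity table, the percentile table,
    the cumulative avoided-deaths ranges vs current policy, and the
    per-capita deaths table.  Requires current_policy among the
    results."""
    if "current_policy" not in results:
        raise ValueError("comparisons require the current_policy scenario")
    exposure = pd.concat([r.exposure for r in results.values()], ignore_index=True)
    base = results["current_policy"].deaths
    avoided_rows = []
    for name, r in results.items():
        if name == "current_policy":
            continue
        a = avoided_deaths(r.deaths, base)
        row = {"scenario": name, "avoided_min": a["min"], "avoided_max": a["max"]}
        row.update({f"avoided_{v}": x for v, x in a["by_variant"].items()})
        avoided_rows.append(row)
    pc_rows = []
    for name, r in results.items():
        for variant in sorted(r.deaths["variant"].unique()):
            for g in GROUPS:
                pc_rows.append(
                    {
                        "scenario": name,
                        "variant": variant,
                        "group": g,
                        "period": 2030,
                        "deaths_per_100k": per_capita_deaths(
                            r.deaths, inputs.population, g, 2030, variant
                        ),
                    }
                )
    return {
        "exposure": exposure,
        "avoided_deaths": pd.DataFrame(avoided_rows),
        "per_capita_2030": pd.DataFrame(pc_rows),
    }


def write_artifacts(config: RunConfig, results: dict, inputs: Inputs, outdir=None) -> Path:
    """Persist all artifacts as CSV/GeoJSON plus a run manifest."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counties_to_geojson(inputs.counties, out / "counties.geojson")
    write_csv(inputs.population, out / "population.csv")
    write_csv(inputs.egu_fleet, out / "egu_fleet.csv")
    for name, r in results.items():
        d = out / name
        d.mkdir(exist_ok=True)
        write_csv(r.county_emissions, d / "county_emissions.csv")
        write_csv(r.field, d / "concentration_field.csv")
        write_csv(r.exposure, d / "exposure_summary.csv")
        write_csv(r.deaths, d / "deaths.csv")
    tables = compare_scenarios(results, inputs) if "current_policy" in results and len(results) > 1 else {}
    for name, df in tables.items():
        write_csv(df, out / f"compare_{name}.csv")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "scenarios": sorted(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
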