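import numpy as np
import pandas as pd
import pytest

from aqequity.pipeline import RunConfig, generate_inputs
from aqequity.synth import gen_counties, gen_population, DemographicTrajectory


@pytest.fixture(scope="session")
def smoke_config():
    """Tiny 2-region configuration for fast end-to-end runs."""
    return RunConfig(
        seed=11,
        n_regions=2,
        counties_per_region=3,
        domain_size_km=600.0,
        base_population=2e6,
        n_clusters=4,
        units_per_cluster=2,
    )


@pytest.fixture(scope="session")
def smoke_inputs(smoke_config):
    return generate_inputs(smoke_config)


@pytest.fixture(scope="session")
def counties20():
    """20-county, 4-region geography for oracle comparisons."""
    return gen_counties(4, 5, 1200.0, seed=3)


@pytest.fixture(scope="session")
def population20(counties20):
    return gen_population(counties20, DemographicTrajectory(), 5e6, seed=4)


@pytest.fixture()
def two_county_field():
    """The worked exposure example: concentrations 2 and 1."""
    return pd.DataFrame(
        {"county_id": ["c1", "c2"], "period": 2020, "conc": [2.0, 1.0]}
    )


def make_pop(county_pops: dict, group: str = "g", period: int = 2020) -> pd.DataFrame:
    """Minimal population table: one group, one adult age band."""
    return pd.DataFrame(
        [
            {
                "county_id": c,
                "group": group,
                "age_band": "30-64",
                "period": period,
                "persons": p,
            }
            for c, p in county_pops.items()
        ]
    )
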