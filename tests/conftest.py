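import numpy as np
import pytest

from driglucose import (
    ScenarioConfig,
    StreetNetwork,
    gen_census_areas,
    gen_ndvi_raster,
    gen_street_network,
    simulate_scenario,
)


@pytest.fixture
def line_network():
    """A - B - C chain, 100 m edges, along the x axis."""
    coords = {"A": (0.0, 0.0), "B": (100.0, 0.0), "C": (200.0, 0.0)}
    return StreetNetwork.from_arrays(coords, [("A", "B"), ("B", "C")])


@pytest.fixture
def grid_network():
    """Regular 5x5 lattice, 100 m spacing (deterministic: irregularity 0)."""
    cfg = ScenarioConfig(
        extent=(0, 0, 400, 400), street_spacing=100, street_irregularity=0.0,
        n_census_areas=4, n_participants=10, seed=1,
    )
    return gen_street_network(cfg)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        extent=(0, 0, 1200, 1200),
        street_spacing=120,
        street_irregularity=0.2,
        n_census_areas=30,
        ses_spatial_range=400,
        ndvi_smoothness=150,
        ndvi_ses_coupling=-0.4,
        n_participants=120,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    """One shared synthetic study area (1.2 km, 30 census areas, 120 people)."""
    return simulate_scenario(small_config)


@pytest.fixture(scope="session")
def small_areas(small_config):
    return gen_census_areas(small_config)


@pytest.fixture(scope="session")
def small_ndvi(small_config, small_areas):
    return gen_ndvi_raster(small_config, small_areas)
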