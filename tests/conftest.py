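import warnings

import numpy as np
import pytest

from cfimpact import ScenarioConfig, generate_scenario
from cfimpact.synthetic_landscape import generate_surfaces, place_zones, simulate_panel


def small_config(**overrides) -> ScenarioConfig:
    """A 32x32 desk scenario small enough for per-test generation."""
    defaults = dict(
        grid_rows=32,
        grid_cols=32,
        n_zones=3,
        establishment_years=(1997, 2003, 2008),
        zone_target_area=30,
        seed=7,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def tiny_config() -> ScenarioConfig:
    return small_config()


@pytest.fixture(scope="session")
def demo_scene():
    """One medium scenario shared by read-only tests (64x64, 4 zones)."""
    config = small_config(grid_rows=64, grid_cols=64, n_zones=4,
                          zone_target_area=60, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surfaces, zones, truth, panel = generate_scenario(config)
    return {"config": config, "surfaces": surfaces, "zones": zones,
            "truth": truth, "panel": panel}


@pytest.fixture(scope="session")
def base_scene():
    """Scenario parts BEFORE effect injection (for injection tests)."""
    config = small_config(grid_rows=64, grid_cols=64, n_zones=4,
                          zone_target_area=60, seed=11)
    surfaces = generate_surfaces(config)
    panel = simulate_panel(config, surfaces)
    zones, truth = place_zones(config, surfaces, panel)
    return {"config": config, "surfaces": surfaces, "panel": panel,
            "zones": zones, "truth": truth}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230928)
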