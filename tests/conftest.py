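import numpy as np
import pandas as pd
import pytest

from dietpattern import SimulationConfig, generate_consumption, generate_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but structured population for fast unit tests."""
    return SimulationConfig(
        n_individuals=300, n_food_groups=30, n_cs=4, n_patterns=4, seed=11
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    truth = generate_truth(small_config)
    X = generate_consumption(truth, small_config)
    return truth, X


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_composition() -> pd.DataFrame:
    """Three foods plus a beverage with round numbers for hand checks."""
    return pd.DataFrame(
        {
            "energy_kcal": [200.0, 100.0, 400.0, 0.0],
            "vitamin_c_mg": [10.0, 50.0, 0.0, 0.0],
            "is_beverage": [False, False, False, True],
        },
        index=pd.Index(["bread", "fruit", "butter", "water"], name="food_group"),
    )
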