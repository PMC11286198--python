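import numpy as np
import pandas as pd
import pytest

from beescape.simulate import SimParams, full_dataset


@pytest.fixture(scope="session")
def preset_data():
    """One full synthetic study at default (study-scale) dimensions."""
    return full_dataset(SimParams(seed=7))


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down dimensions for fast model-fitting tests."""
    return SimParams(n_sites=10, n_bee_species=15, n_plant_species=20, seed=11)


@pytest.fixture(scope="session")
def small_data(small_params):
    return full_dataset(small_params)


@pytest.fixture()
def toy_taxonomy():
    return pd.DataFrame(
        {
            "species": ["A1", "A2", "A3", "B1", "B2", "C1"],
            "genus": ["Ga", "Ga", "Ga", "Gb", "Gb", "Gc"],
            "family": ["Fa", "Fa", "Fa", "Fa", "Fa", "Fc"],
            "origin": ["native"] * 6,
            "flower_unit": ["flower"] * 6,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
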