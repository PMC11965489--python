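import numpy as np
import pandas as pd
import pytest

import fieldsig as fs
from fieldsig.sim import true_methylomes


@pytest.fixture(scope="session")
def small_config():
    """Compact three-tissue discovery scenario with planted effects."""
    return fs.ScenarioConfig(
        seed=11,
        n_cpgs=2000,
        tissues=("mammary_gland", "cervix", "liver"),
        n_per_group=5,
        effect_size_hyper=0.2,
        effect_size_hypo=0.2,
        n_affected_hyper=200,
        n_affected_hypo=200,
        noise_sd=0.01,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return fs.simulate_discovery_cohort(small_config)


@pytest.fixture(scope="session")
def four_type_model():
    return fs.CellTypeModel(
        cell_types=("epithelial", "fibroblast", "fat", "immune"),
        n_cpgs=1000,
        markers_per_type=100,
        marker_delta=0.6,
    )


@pytest.fixture(scope="session")
def four_type_truth(four_type_model):
    """Noise-free cell-type methylomes of the four-type model."""
    return true_methylomes(four_type_model, seed=2)


@pytest.fixture()
def toy_records():
    """Six subjects, distinct times, mixed censoring."""
    return pd.DataFrame(
        {
            "time": [2.0, 4.0, 5.0, 7.0, 9.0, 12.0],
            "event": [1, 1, 0, 1, 0, 1],
        },
        index=[f"m{i}" for i in range(6)],
    )
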