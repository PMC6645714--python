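import numpy as np
import pytest

from antisaccade.params import POOLED_PARAMS
from antisaccade.race_model import simulate_dataset

URGENT_GAPS = [0.0, 75.0, 100.0, 125.0, 150.0, 175.0, 200.0, 250.0, 350.0]


@pytest.fixture(scope="session")
def high_lum_trials():
    """Mid-sized high-luminance simulation shared across tests."""
    df = simulate_dataset({"high": POOLED_PARAMS["high"]}, URGENT_GAPS,
                          40000, seed=1234)
    return df[df["outcome_class"] != "no_response"]


@pytest.fixture
def rng():
    return np.random.default_rng(99)
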