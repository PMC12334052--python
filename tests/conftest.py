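import numpy as np
import pytest

from presyn import load_config


@pytest.fixture(scope="session")
def default_config():
    return load_config(None)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spatial_config():
    """A scaled-down system for particle-engine tests."""
    return load_config(
        {
            "kinetics": {"k2": 1.0e7},
            "counts": {"n_ca": 300, "n_drug": 150, "n_vesicle": 300},
            "t_end": 0.01,
        }
    )
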