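import numpy as np
import pytest
from hypothesis import settings

from focimetry.io import Channel, Treatment
from focimetry.simulate import SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact field for fast pipeline tests: 640x640 px, 12 cells."""
    return SimulationConfig(field_shape_px=(640, 640), n_cells=12, seed=1)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        field_shape_px=(640, 640), n_cells=8, shot_noise=False, read_noise_sd=0.0, seed=2
    )


@pytest.fixture(scope="session")
def trained_model(small_config):
    """Spot classifier trained on simulated fields, shared across tests."""
    from focimetry.pipeline import train_spot_classifier

    return train_spot_classifier(small_config, n_fields=6, seed=100)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
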