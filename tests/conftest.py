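import numpy as np
import pytest

from stua import ModelConfig, initialize_town


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    """Desk-scale town: 8x8 grid, 10 agents, 3 outlets."""
    return ModelConfig(
        grid_width=8,
        grid_height=8,
        n_agents=10,
        n_outlets=3,
        n_workplaces=20,
        days=30,
    )


@pytest.fixture(scope="session")
def small_town(small_config):
    return initialize_town(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
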