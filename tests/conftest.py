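import numpy as np
import pytest

from virtrial import ModelConfig, ParameterSet, build_life_table


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def life_table_70(base_params, config):
    return build_life_table(
        base_params.q70_background.base,
        70,
        config.horizon_cycles,
        config.background_doubling_years,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210705)
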