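import copy

import pytest

from rheumcea import load_bundled_config
from rheumcea.parameters import ModelConfig


@pytest.fixture(scope="session")
def zanzibar() -> ModelConfig:
    return load_bundled_config("zanzibar")


@pytest.fixture()
def config(zanzibar) -> ModelConfig:
    """Mutable per-test copy of the base-case configuration."""
    return copy.deepcopy(zanzibar)


def degenerate_config(base: ModelConfig) -> ModelConfig:
    """Collapse every uncertainty range onto its point estimate."""
    from rheumcea.parameters import uncertainty_parameters

    cfg = copy.deepcopy(base)
    for p in uncertainty_parameters(cfg).values():
        param = p.get(cfg)
        param.low = param.high = param.value
    return cfg


@pytest.fixture()
def zero_mortality_config(config) -> ModelConfig:
    config.mortality.baseline_annual_mortality.value = 0.0
    config.mortality.baseline_annual_mortality.low = 0.0
    config.mortality.baseline_annual_mortality.high = 0.0
    return config
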