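import dataclasses

import pytest

from tdmassay import AssayGeometry, ResponseModel, RunConfig


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig().validate()


@pytest.fixture
def noiseless_config(default_config: RunConfig) -> RunConfig:
    """Config with every stochastic element of the instrument switched off."""
    geometry = dataclasses.replace(default_config.assay.geometry, baseline_noise_sd=0.0)
    response = dataclasses.replace(
        default_config.assay.response, proportional_cv=0.0, rt_jitter_sd=0.0, day_effect_sd=0.0
    )
    assay = dataclasses.replace(default_config.assay, geometry=geometry, response=response)
    return dataclasses.replace(default_config, assay=assay).validate()


@pytest.fixture
def noiseless_geometry() -> AssayGeometry:
    return AssayGeometry(baseline_noise_sd=0.0)


@pytest.fixture
def noiseless_response() -> ResponseModel:
    return ResponseModel(proportional_cv=0.0, rt_jitter_sd=0.0)
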