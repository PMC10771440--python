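import numpy as np
import pytest

from sigrekin import expression_profiles as ep
from sigrekin import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config():
    return sd.SimulationConfig(noise_sd_log2=0.0)


@pytest.fixture(scope="session")
def regulators(sim_config):
    return sd.canonical_regulators(sim_config)


@pytest.fixture(scope="session")
def sigE_preprocessed(regulators):
    return ep.preprocess_profile(ep.log_expression(regulators["sigE"]))


@pytest.fixture(scope="session")
def hrdB_preprocessed(regulators):
    return ep.preprocess_profile(ep.log_expression(regulators["hrdB"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
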