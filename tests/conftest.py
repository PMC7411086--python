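import numpy as np
import pytest

from phaeotox.synthetic import ExperimentConfig, generate_bundle


@pytest.fixture(scope="session")
def noiseless_config():
    return ExperimentConfig(noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return generate_bundle(noiseless_config)


@pytest.fixture(scope="session")
def noisy_config():
    return ExperimentConfig(noise_cv=0.1, seed=11)


@pytest.fixture(scope="session")
def noisy_bundle(noisy_config):
    return generate_bundle(noisy_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
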