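import pytest
from hypothesis import settings

from bbbpk import default_config, run_pipeline, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_config():
    return default_config(noise=False)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return simulate_study(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_dataset):
    return run_pipeline(noiseless_dataset)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_study(default_config(noise=True, seed=1234))
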