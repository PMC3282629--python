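import pytest

import renofur as rf


@pytest.fixture(scope="session")
def default_config():
    return rf.SimulationConfig()


@pytest.fixture(scope="session")
def truth(default_config):
    return rf.ground_truth_fur(default_config)


@pytest.fixture(scope="session")
def noise_free_study(default_config):
    return rf.simulate_study(default_config)


@pytest.fixture(scope="session")
def noise_free_result(noise_free_study):
    return rf.analyze_study(noise_free_study.curves)


@pytest.fixture(scope="session")
def rendered_study(default_config):
    return rf.simulate_study(default_config, render=True)
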