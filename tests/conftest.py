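import pytest

from iasrisk import ScenarioConfig, load_default_config, run_scenario


@pytest.fixture(scope="session")
def params():
    return load_default_config()


@pytest.fixture(scope="session")
def lb_run(params):
    """A moderate-size lower-bound run shared across unit tests."""
    scenario = ScenarioConfig.lower_bound(n_iterations=4000, random_seed=7)
    return run_scenario(scenario, params)


@pytest.fixture(scope="session")
def ub_run(params):
    scenario = ScenarioConfig.upper_bound(n_iterations=4000, random_seed=7)
    return run_scenario(scenario, params)
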