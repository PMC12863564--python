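import pytest

import excisesim as ex


@pytest.fixture(scope="session")
def moz():
    return ex.mozambique()


@pytest.fixture(scope="session")
def market(moz):
    return moz.market


@pytest.fixture(scope="session")
def macro(moz):
    return moz.macro


@pytest.fixture(scope="session")
def scenarios(moz):
    return {s.name: s for s in ex.build_scenarios(moz.market, moz.macro, moz.scenarios)}


@pytest.fixture(scope="session")
def prevalence_model(moz):
    return ex.prevalence_model_from_config(moz)


@pytest.fixture(scope="session")
def results_linear(moz, scenarios, prevalence_model):
    return {
        name: ex.run_scenario(
            moz.market, moz.macro, scenario, prevalence_model, demand_form="linear"
        )
        for name, scenario in scenarios.items()
    }


@pytest.fixture(scope="session")
def results_power(moz, scenarios, prevalence_model):
    return {
        name: ex.run_scenario(
            moz.market, moz.macro, scenario, prevalence_model, demand_form="power"
        )
        for name, scenario in scenarios.items()
    }
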