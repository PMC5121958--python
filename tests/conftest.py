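import pytest

from phaseflux import (
    SyntheticScenario,
    make_growth_curve,
    make_toy_model,
    parameterize,
    run_phase_fba,
    run_phase_fva,
    run_moma_chain,
)

SEED = 1


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=SEED)


@pytest.fixture(scope="session")
def curve(scenario):
    return make_growth_curve(scenario)


@pytest.fixture(scope="session")
def params(curve):
    return parameterize(curve)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(6, seed=SEED)


@pytest.fixture(scope="session")
def fba(toy_model, params):
    return run_phase_fba(toy_model, params)


@pytest.fixture(scope="session")
def fva(toy_model, params):
    return run_phase_fva(toy_model, params)


@pytest.fixture(scope="session")
def chain(toy_model, params, fba):
    return run_moma_chain(toy_model, params, fba_fluxes=fba)
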