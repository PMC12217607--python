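import pytest

import foodshift as fs


@pytest.fixture(scope="session")
def fixture_seed1():
    return fs.generate_fixture(seed=1)


@pytest.fixture(scope="session")
def ef_default():
    return fs.EmissionFactorTable.default()


@pytest.fixture(scope="session")
def bau_demand(fixture_seed1):
    """Business-as-usual demand table under the 3220-kcal benchmark."""
    kcal0, shares0 = fs.baseline_diet(fixture_seed1)
    conv = fs.convergence_spec_from_fixture(fixture_seed1)
    pop = fs.population_path_from_fixture(fixture_seed1)
    path = fs.project_diet_path(kcal0, shares0, conv)
    return fs.compute_demand(pop, path)
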