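import numpy as np
import pytest

from kcatevo.evolution import build_constrained_set, initial_kcats
from kcatevo.fixtures import (
    FixtureSpec,
    make_dre_fixture,
    make_isozyme_branch,
    make_linear_pathway,
    make_mixed_model,
    make_multifunctional_model,
    make_standard_fixture,
    make_trajectory_toy,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def linear5():
    return make_linear_pathway(FixtureSpec(n_reactions=5))


@pytest.fixture(scope="session")
def multifunctional():
    return make_multifunctional_model()


@pytest.fixture(scope="session")
def isozyme():
    return make_isozyme_branch()


@pytest.fixture(scope="session")
def mixed():
    return make_mixed_model()


@pytest.fixture(scope="session")
def standard():
    model, spec = make_standard_fixture()
    return model, spec, build_constrained_set(model)


@pytest.fixture(scope="session")
def trajectory_toy():
    model, spec = make_trajectory_toy()
    return model, spec, build_constrained_set(model)


@pytest.fixture(scope="session")
def dre():
    model, spec = make_dre_fixture()
    return model, spec, build_constrained_set(model)
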