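import numpy as np
import pytest

from crnpf import fixtures
from crnpf.network import build_network


@pytest.fixture(scope="session")
def dimer_params():
    return dict(fixtures.PARAMS_DIMER)


@pytest.fixture(scope="session")
def reversible_pair():
    """2*S1 <-> S2 with unit rate constants."""
    return build_network(
        ["S1", "S2"],
        [
            {"reactants": {"S1": 2}, "products": {"S2": 1}, "rate_constant": 1.0},
            {"reactants": {"S2": 1}, "products": {"S1": 2}, "rate_constant": 1.0},
        ],
    )


@pytest.fixture(scope="session")
def birth_death():
    """0 <-> S with birth rate 3 and unit per-capita death rate."""
    return build_network(
        ["S"],
        [
            {"reactants": {}, "products": {"S": 1}, "rate_constant": 3.0,
             "label": "birth"},
            {"reactants": {"S": 1}, "products": {}, "rate_constant": 1.0,
             "label": "death"},
        ],
    )


@pytest.fixture(scope="session")
def full_system(dimer_params):
    return fixtures.full_dimer_system(dimer_params)


@pytest.fixture(scope="session")
def constrained_system(dimer_params):
    """The constrained pair as written out in the source text."""
    return fixtures.constrained_pair(dimer_params, fold_degradation=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
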