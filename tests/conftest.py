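import numpy as np
import pytest

from nkhif import build_default_parameters, solve_consistent_equilibrium


@pytest.fixture(scope="session")
def params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def eq(params):
    """Published parameters made exactly consistent with the untreated
    equilibrium, plus the equilibrium state itself."""
    return solve_consistent_equilibrium(params)


@pytest.fixture(scope="session")
def zero_params(params):
    """All rate constants zero (the null system)."""
    p = params.copy()
    for name in p.values:
        p.values[name] = 0.0
    p.roles = {n: "fixed" for n in p.values}
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
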