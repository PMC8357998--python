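import numpy as np
import pytest
from hypothesis import settings

import latentchange as lc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def uni_spec():
    return lc.ModelSpec(n_processes=1, n_occasions=5)


@pytest.fixture
def uni_params():
    """Deterministic univariate dual model: decelerated growth toward 6."""
    return lc.ParameterSet(
        mu0=[2.0],
        mua=[3.0],
        phi=[[1.0, -0.1], [-0.1, 0.3]],
        beta=[-0.5],
        theta=[[0.5]],
    )


@pytest.fixture
def uni_stoch_spec():
    return lc.ModelSpec(n_processes=1, stochastic=True, n_occasions=5)


@pytest.fixture
def uni_stoch_params(uni_params):
    return lc.ParameterSet(
        mu0=uni_params.mu0,
        mua=uni_params.mua,
        phi=uni_params.phi,
        beta=uni_params.beta,
        theta=uni_params.theta,
        psi=[[0.3]],
    )


@pytest.fixture
def biv_spec():
    return lc.ModelSpec(n_processes=2, n_occasions=4)


@pytest.fixture
def biv_params():
    phi = np.diag([1.0, 1.0, 0.3, 0.3])
    phi[0, 1] = phi[1, 0] = 0.2
    return lc.ParameterSet(
        mu0=[0.0, 1.0],
        mua=[1.0, 0.5],
        phi=phi,
        beta=[-0.3, -0.4],
        gamma=[0.1, -0.2],
        theta=[[0.5, 0.1], [0.1, 0.6]],
    )


@pytest.fixture
def biv_stoch_spec():
    return lc.ModelSpec(n_processes=2, stochastic=True, n_occasions=4)


@pytest.fixture
def biv_stoch_params(biv_params):
    return lc.ParameterSet(
        mu0=biv_params.mu0,
        mua=biv_params.mua,
        phi=biv_params.phi,
        beta=biv_params.beta,
        gamma=biv_params.gamma,
        theta=biv_params.theta,
        psi=[[0.2, 0.05], [0.05, 0.3]],
    )
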