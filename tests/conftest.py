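import numpy as np
import pytest

from kiss_sim import GridSpec, KissModel, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def grid1d():
    return build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=41, bc="dirichlet0"))


@pytest.fixture
def grid2d():
    return build_grid(GridSpec(dim=2, lo=-1.0, hi=1.0, N=21, bc="dirichlet0"))


@pytest.fixture
def linear_model():
    return KissModel(D=1.0, tau=1.0, alpha=1.0)
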