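import numpy as np
import pytest

from fibrilscape.saxs_model import SAXSModelParams
from fibrilscape.synthetic import NoiseSpec, gen_saxs_curve


@pytest.fixture(scope="session")
def q_grid():
    """200-point log-spaced grid over the instrument's q range."""
    return np.geomspace(0.05, 1.0, 200)


@pytest.fixture(scope="session")
def truth_params():
    """Ground truth mirroring the uninhibited condition: cross-section
    2r = 12 nm, stacking distance d = 24 nm."""
    return SAXSModelParams(A=1.0, r=6.0, sigma_r=0.25, L=1000.0, d=24.0,
                           nu=1.0, B=1e-3, n_exp=1.3, C=1e-4)


@pytest.fixture(scope="session")
def noiseless_profile(truth_params, q_grid):
    return gen_saxs_curve(truth_params, q_grid, NoiseSpec(kind="none"))


@pytest.fixture(scope="session")
def noisy_profile(truth_params, q_grid):
    return gen_saxs_curve(
        truth_params, q_grid,
        NoiseSpec("multiplicative-gaussian", 0.02, seed=42))
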