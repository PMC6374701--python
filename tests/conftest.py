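import numpy as np
import pytest

from petomics.config import CohortConfig
from petomics.kinetics import KineticParameters, feng_input_function, solve_two_tissue


@pytest.fixture(scope="session")
def cp():
    return feng_input_function()


@pytest.fixture(scope="session")
def typical_params():
    return KineticParameters(k1=0.15, k2=0.4, k3=0.1, k4=0.01, vb=0.05)


@pytest.fixture(scope="session")
def typical_tac(typical_params, cp):
    return solve_two_tissue(typical_params, cp)


@pytest.fixture()
def small_cohort():
    return CohortConfig(
        n_patients=30, n_genes=500, n_de_genes=50, n_linked_genes=20, seed=7
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
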