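import numpy as np
import pytest

from pvin import bifurcation as bf
from pvin.params import PVINParameters, load_params


@pytest.fixture(scope="session")
def params() -> PVINParameters:
    return load_params("ca1_chamberland_modified")


@pytest.fixture(scope="session")
def passive_params(params) -> PVINParameters:
    """Leak-only cell: every voltage-gated conductance removed."""
    return params.replace(g_Kv3=0.0, g_Kv1=0.0, g_Na=0.0)


@pytest.fixture(scope="session")
def branch_450(params):
    """Frozen-q equilibrium branch at the canonical 450 pA hold."""
    return bf.continue_equilibria(params, 450.0, (0.4, 0.0))


@pytest.fixture(scope="session")
def hopf_450(params, branch_450):
    hopfs = bf.detect_hopf(branch_450, params, I_app_pA=450.0)
    assert len(hopfs) == 1
    return hopfs[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240704)
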