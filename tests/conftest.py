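import numpy as np
import pytest

from colocscreen.ldpanel import compute_ld
from colocscreen.simulate import simulate_panel


@pytest.fixture(scope="session")
def panel():
    """Block-LD diploid panel shared across tests (800 haplotypes, 100 variants)."""
    return simulate_panel(n_hap=800, n_var=100, block_len=10, rho=0.9, seed=11)


@pytest.fixture(scope="session")
def ld(panel):
    return compute_ld(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
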