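import numpy as np
import pytest

from structgp import SimConfig, simulate_cohort, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cohort():
    """Default-composition cohort at a desk-scale marker count."""
    cfg = SimConfig(n_markers=400, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_trait(small_cohort):
    G, _ = small_cohort
    y, arch = simulate_phenotypes(G, h2=0.6, n_qtl=40, seed=12)
    return y, arch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
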