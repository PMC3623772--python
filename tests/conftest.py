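import numpy as np
import pytest

from balsel import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scenario():
    """One realisation of the default two-haplogroup locus scenario."""
    cfg = synthdata.SubstructureConfig(seed=2024)
    m, truth = synthdata.simulate_substructure_locus(cfg)
    return cfg, m, truth


def random_haplotype_matrix(rng, n=10, n_sites=20):
    """A dense random 0/1 matrix for oracle-equivalence checks."""
    return rng.integers(0, 2, size=(n, n_sites)).astype(np.int8)
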