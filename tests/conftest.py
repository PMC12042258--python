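import numpy as np
import pytest

from coevmatch.simulate import generate_paired_msa


@pytest.fixture(scope="session")
def coupled_pa():
    """Small strongly coupled family: native pairing is the information optimum."""
    return generate_paired_msa(6, 15, coupling=1.0, noise=0.0, seed=11)


@pytest.fixture(scope="session")
def clustered_pa():
    """Family with four clusters of similar sequences and moderate coupling."""
    return generate_paired_msa(24, 12, coupling=0.8, n_clusters=4, noise=0.15, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
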