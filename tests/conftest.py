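import numpy as np
import pytest

from mmrsig import simulate


@pytest.fixture(scope="session")
def sim_genome():
    """A 200 kb synthetic genome with worm-like GC and its homopolymer census."""
    genome, census = simulate.simulate_genome(200_000, gc=0.36, seed=11)
    return genome, census


@pytest.fixture
def tiny_genome():
    # chrT: positions laid out for context and homopolymer tests
    return {
        "chrT": "GGATTACAAAAAGCTTTTTTTTTCGATCGATCGGGGGACACACACACTT",
        "chrU": "ACGTACGTACAACA",
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
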