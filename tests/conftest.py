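import numpy as np
import pytest

from darkbin import simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ancestor_pair():
    """A 100 kb ancestor and a 5% divergent child, with the truth table."""
    anc = simulate.GenomeSpec(id="anc", length=100_000, gc_target=0.45)
    child = simulate.GenomeSpec(
        id="child", length=100_000, gc_target=0.45, divergence_from_parent=0.05
    )
    genomes, truth = simulate.evolve_genome_set(anc, [child], seed=7)
    return genomes, truth
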