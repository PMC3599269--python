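import numpy as np
import pytest

from arborator import simulate as sim


@pytest.fixture(scope="session")
def small_pair():
    """A modest genome pair with rearrangements and known truth."""
    genome, genes = sim.simulate_ancestor(2, 60, 200, rng_seed=17)
    params = sim.EvolutionParams(sub_rate=0.02, gene_loss_prob=0.02,
                                 n_inversions=1, n_translocations=1,
                                 rng_seed=18)
    derived, derived_genes, truth = sim.evolve(genome, genes, params)
    return genome, genes, derived, derived_genes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
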