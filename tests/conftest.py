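import dendropy
import numpy as np
import pytest

from genelosskit.gene_models import read_newick
from genelosskit.simulate import SimulationConfig, simulate_gene_family


@pytest.fixture(scope="session")
def four_taxon_tree() -> dendropy.Tree:
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


def small_sim_config(seed: int, **overrides) -> SimulationConfig:
    """Compact gene (same 19-exon architecture, short introns) so tests
    stay fast; detection behavior does not depend on intron length."""
    defaults = dict(
        seed=seed,
        n_exons=19,
        exon_length_range=(60, 90),
        intron_length_range=(80, 160),
        flank_length=100,
        substitution_rate=0.01,
        indel_rate=0.001,
        loss_branches=frozenset([frozenset({"A", "B"})]),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def simulated_family(four_taxon_tree):
    return simulate_gene_family(four_taxon_tree, small_sim_config(11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130401)
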