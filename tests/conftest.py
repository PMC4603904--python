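import dendropy
import numpy as np
import pytest
from hypothesis import settings

import anchortree as at
from anchortree.simulate import scale_to_min_internal

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             rooting="default-rooted")
    tree.is_rooted = True
    return tree


def yule_tree(n_species: int, seed: int, min_internal: float | None = None):
    cfg = at.SimulationConfig(n_species=n_species, n_loci=1, seed=seed)
    tree = at.simulate_species_tree(cfg)
    if min_internal is not None:
        tree = scale_to_min_internal(tree, min_internal)
    return tree


@pytest.fixture(scope="session")
def small_dataset():
    """10 pseudo-samples x 6 loci with 1% read error; reused across tests."""
    cfg = at.SimulationConfig(
        n_species=4, n_loci=3, per_base_error_rate=0.01, coverage=20.0,
        missing_fraction=0.0, seed=11)
    return at.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pair(rng, frag_len=200, read_len=150, qual=35):
    from anchortree._seq import revcomp
    frag = "".join(rng.choice(list("ACGT"), frag_len))
    r1, r2 = frag[:read_len], revcomp(frag)[:read_len]
    return at.ReadPair("p", r1, np.full(len(r1), qual),
                       r2, np.full(len(r2), qual))
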