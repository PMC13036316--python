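import numpy as np
import pytest

from traitscape import phylogeny as phy
from traitscape import synthetic_data as synth
from traitscape import traits as tr


@pytest.fixture(scope="session")
def small_tree():
    return synth.gen_phylogeny(12, seed=7)


@pytest.fixture(scope="session")
def small_cov(small_tree):
    C, labels = phy.phylo_covariance(small_tree)
    return C, labels


@pytest.fixture(scope="session")
def small_config():
    return synth.SimConfig(n_species=12, n_x=4, n_y=4, seed=7)


@pytest.fixture(scope="session")
def complete_traits(small_tree):
    cfg = synth.SimConfig(n_species=12, n_x=4, n_y=4, seed=7, missing_rate=0.0)
    return synth.gen_traits(small_tree, cfg)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return synth.gen_landscape(small_config)


@pytest.fixture(scope="session")
def small_sim(small_tree, complete_traits, small_landscape, small_config):
    return synth.gen_occurrences(
        small_tree, complete_traits, small_landscape, small_config
    )


def star_tree(n, depth=1.0):
    """Star phylogeny: all tips attach directly to the root."""
    nwk = "(" + ",".join(f"T{i}:{depth}" for i in range(n)) + ");"
    return phy.read_newick_string(nwk)


@pytest.fixture(scope="session")
def gower_oracle():
    """Brute-force per-column weighted Gower for small tables."""

    def _oracle(table: tr.TraitTable, weights: tr.GowerWeights):
        import numpy as np

        S = len(table.species)
        D = np.zeros((S, S))
        for i in range(S):
            for j in range(S):
                num = den = 0.0
                for col in table.continuous:
                    x = table.data[col].to_numpy(float)
                    rng = x.max() - x.min()
                    c = abs(x[i] - x[j]) / rng if rng > 0 else 0.0
                    w = weights.weights[col]
                    num += w * c
                    den += w
                for col in table.binary:
                    x = table.data[col].to_numpy(float)
                    w = weights.weights[col]
                    num += w * (1.0 if x[i] != x[j] else 0.0)
                    den += w
                D[i, j] = num / den
        return D

    return _oracle
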