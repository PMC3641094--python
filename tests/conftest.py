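import numpy as np
import pytest
import scipy.sparse as sp

from phenowalk.network import (
    BipartiteAssociations,
    GeneIndex,
    TraitIndex,
    TraitSimilarity,
    assemble,
    load_associations,
    load_gene_network,
)
from phenowalk.synthetic import SyntheticConfig, generate


def random_heterogeneous_net(rng, n_genes=8, n_target=3, n_other=2,
                             p_edge=0.4, p_assoc=0.35, with_sim=True):
    """A small random heterogeneous network for randomized identity checks."""
    genes = GeneIndex.from_ids([f"g{i}" for i in range(n_genes)])
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                edges.append((f"g{i}", f"g{j}", float(rng.uniform(0.1, 1.0))))
    if not edges:
        edges = [("g0", "g1", 0.5)]
    gene_net = load_gene_network(edges, genes=genes)

    def bip(species, n_traits):
        rows = [(f"g{i}", f"{species}:t{j}")
                for i in range(n_genes) for j in range(n_traits)
                if rng.random() < p_assoc]
        traits = TraitIndex.from_ids(species, [f"{species}:t{j}" for j in range(n_traits)])
        return load_associations(rows, genes, species, traits=traits)

    target = bip("target", n_target)
    others = [bip(f"sp{s}", 2) for s in range(n_other)]
    sim = None
    if with_sim:
        m = np.zeros((n_target, n_target))
        for i in range(n_target):
            for j in range(i + 1, n_target):
                if rng.random() < 0.6:
                    m[i, j] = m[j, i] = rng.uniform(0.05, 0.9)
        sim = TraitSimilarity(target.traits, sp.csr_matrix(m))
    return assemble(gene_net, [target, *others], sim)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_world():
    """Small fast world for pipeline tests."""
    return generate(SyntheticConfig(
        n_genes=60, n_modules=4, n_traits_target=8, n_species=2,
        traits_per_species=5, genes_per_trait=4, genes_per_species_trait=4,
        seed=11,
    ))


@pytest.fixture(scope="session")
def default_world():
    """One world at the default study conditions."""
    return generate(SyntheticConfig(seed=7))
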