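import numpy as np
import pytest
import scipy.sparse as sp

from pacer.network import GeneNetwork, PathwayCollection, build_heterogeneous_network


def make_network(A, gene_ids=None):
    A = np.asarray(A, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(A.shape[0])]
    return GeneNetwork(gene_ids=list(gene_ids), adjacency=sp.csr_matrix(A))


def random_network(rng, n, density=0.3):
    """Random symmetric weighted graph with zero diagonal."""
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    A = np.triu(W, 1)
    A = A + A.T
    return make_network(A)


def random_pathways(rng, gene_ids, m, mean_size=4):
    n = len(gene_ids)
    B = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        size = max(1, rng.poisson(mean_size))
        B[rng.choice(n, min(size, n), replace=False), j] = 1
    return PathwayCollection(
        pathway_ids=[f"P{j}" for j in range(m)], membership=B, gene_ids=list(gene_ids)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_net():
    # triangle + pendant
    A = np.array(
        [
            [0, 0.9, 0.4, 0],
            [0.9, 0, 0.7, 0],
            [0.4, 0.7, 0, 0.2],
            [0, 0, 0.2, 0],
        ]
    )
    return make_network(A)


@pytest.fixture
def tiny_paths(tiny_net):
    B = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
    return PathwayCollection(
        pathway_ids=["P0", "P1"], membership=B, gene_ids=tiny_net.gene_ids
    )


@pytest.fixture
def tiny_het(tiny_net, tiny_paths):
    return build_heterogeneous_network(tiny_net, tiny_paths)
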