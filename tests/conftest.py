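import numpy as np
import pytest

from algddi.attribute_encoder import MolecularGraph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def chain_graph(n: int) -> MolecularGraph:
    """Unbranched n-carbon chain built directly (no SMILES parsing)."""
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)]) if n > 1 else np.zeros((0, 2), int)
    degree = np.ones(n, dtype=np.int64)
    if n > 1:
        degree[1:-1] = 2
    else:
        degree[:] = 0
    return MolecularGraph(
        atom_type=np.zeros(n, dtype=np.int64),
        degree=degree,
        charge=np.full(n, 2, dtype=np.int64),
        edges=edges,
        bond_type=np.zeros(max(n - 1, 0), dtype=np.int64),
    )


@pytest.fixture
def random_molecular_graph():
    def make(n_nodes: int, seed: int = 0, p_edge: float = 0.3) -> MolecularGraph:
        g_rng = np.random.default_rng(seed)
        edges = []
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if g_rng.random() < p_edge:
                    edges.append((i, j))
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        deg = np.zeros(n_nodes, dtype=np.int64)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        return MolecularGraph(
            atom_type=g_rng.integers(0, 4, n_nodes),
            degree=np.minimum(deg, 6),
            charge=np.full(n_nodes, 2, dtype=np.int64),
            edges=edges,
            bond_type=g_rng.integers(0, 2, len(edges)),
        )

    return make
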