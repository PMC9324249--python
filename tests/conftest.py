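import numpy as np
import pytest

import gliograph as gg


@pytest.fixture(scope="session")
def parc136():
    return gg.make_parcellation(136)


@pytest.fixture(scope="session")
def parc_small():
    """12-ROI two-lobe parcellation for fast end-to-end tests."""
    return gg.make_parcellation(12, {"frontal": 0.5, "temporal": 0.5})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def graph_from_adjacency(adj: np.ndarray) -> gg.BinaryGraph:
    return gg.BinaryGraph(adjacency=adj.astype(bool), node_ids=np.arange(adj.shape[0]))


def named_graph(name: str) -> np.ndarray:
    """Small closed-form graphs: K4, star S5 (center 0), ring C5, path P4."""
    if name == "K4":
        adj = ~np.eye(4, dtype=bool)
    elif name == "S5":
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
    elif name == "C5":
        adj = np.zeros((5, 5), dtype=bool)
        for i in range(5):
            adj[i, (i + 1) % 5] = adj[(i + 1) % 5, i] = True
    elif name == "P4":
        adj = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = True
    else:
        raise ValueError(name)
    return adj
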