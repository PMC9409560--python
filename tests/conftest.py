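import networkx as nx
import pytest

from netoverlap import GeneSet, SimulationConfig, simulate_interactome


@pytest.fixture
def path_graph():
    """Path 1-2-3-4-5 (string node labels)."""
    g = nx.Graph()
    nx.add_path(g, ["1", "2", "3", "4", "5"])
    return g


@pytest.fixture
def star_graph():
    """Star: center c with leaves l1..l4."""
    g = nx.Graph()
    g.add_edges_from([("c", f"l{i}") for i in range(1, 5)])
    return g


@pytest.fixture(scope="session")
def er_background():
    """Seeded sparse background interactome, 2000 nodes, mean degree ~4."""
    return simulate_interactome(
        SimulationConfig(seed=11, n_nodes=2000, graph_model="erdos_renyi",
                         model_params={"p": 0.002})
    )


def random_graph(seed: int, n_max: int = 30, p: float = 0.2) -> nx.Graph:
    """Small random graph with string labels for oracle comparisons."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})


def gene_set(name: str, *genes: str) -> GeneSet:
    return GeneSet(name, tuple(genes))
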