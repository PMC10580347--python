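import networkx as nx
import numpy as np
import pytest

from proxiscreen.network import InteractionNetwork
from proxiscreen.trajectory import AtomLabel, Trajectory


@pytest.fixture
def path_graph_net() -> InteractionNetwork:
    """A-B-C-D path graph."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    return InteractionNetwork(graph=g)


@pytest.fixture
def star_net() -> InteractionNetwork:
    """Hub H with leaves L1..L3."""
    g = nx.Graph()
    g.add_edges_from([("H", "L1"), ("H", "L2"), ("H", "L3")])
    return InteractionNetwork(graph=g)


def random_network(n_nodes: int, p: float, seed: int) -> InteractionNetwork:
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    return InteractionNetwork(graph=g)


def small_trajectory(n_res=5, n_frames=4, seed=0, sd=0.1) -> Trajectory:
    rng = np.random.default_rng(seed)
    ref = np.column_stack([3.8 * np.arange(n_res),
                           np.sin(np.arange(n_res)),
                           np.cos(np.arange(n_res))])
    coords = ref[None] + rng.normal(0, sd, (n_frames, n_res, 3))
    labels = [AtomLabel(i + 1, "CA") for i in range(n_res)]
    return Trajectory(labels, coords, dt=0.1)
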