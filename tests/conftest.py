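import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dims.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def default_study():
    """The default four-arm synthetic study (seed 0)."""
    cfg = SimulationConfig(seed=0)
    matrices, truth = simulate_expression(cfg)
    return cfg, matrices, truth


@pytest.fixture(scope="session")
def intact_study():
    """Five planted modules, no disruption and no DEGs (seed 0)."""
    cfg = SimulationConfig(seed=0, disruption_map={}, deg_map={})
    matrices, truth = simulate_expression(cfg)
    return cfg, matrices, truth


@pytest.fixture
def path_graph():
    """1-2-3-4-5 path with string node names."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in range(5)})


@pytest.fixture
def star_graph():
    """Hub c with leaves l1..l4."""
    g = nx.Graph()
    g.add_edges_from(("c", f"l{i}") for i in range(1, 5))
    return g


def random_connected_graph(rng: np.random.Generator, max_n: int = 8) -> nx.Graph:
    """Small random connected simple graph for oracle-equivalence checks."""
    n = int(rng.integers(4, max_n + 1))
    while True:
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
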