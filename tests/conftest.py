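import numpy as np
import pytest

from connectomestats import Connectome, SimulationConfig, generate_cohort


def graph_from_edges(n, edges):
    """Connectome from {(i, j): w} with 1-based node ids."""
    w = np.zeros((n, n))
    for (i, j), val in edges.items():
        w[i - 1, j - 1] = w[j - 1, i - 1] = val
    return Connectome(weights=w, node_ids=np.arange(1, n + 1))


@pytest.fixture
def five_node():
    """The worked 5-node example: AB:1, AC:5, BC:1, CD:5, DE:5."""
    return graph_from_edges(5, {(1, 2): 1, (1, 3): 5, (2, 3): 1, (3, 4): 5, (4, 5): 5})


@pytest.fixture
def star5():
    """Star: center node 1 with four unit-weight leaves."""
    return graph_from_edges(5, {(1, 2): 1, (1, 3): 1, (1, 4): 1, (1, 5): 1})


@pytest.fixture
def path3():
    return graph_from_edges(3, {(1, 2): 1, (2, 3): 1})


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort (in-memory) for integration-ish tests."""
    cfg = SimulationConfig(n_nodes=40, n_per_group=(8, 8), seed=7)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth
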