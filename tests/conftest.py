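import numpy as np
import pytest

from nethub.graph_core import UndirectedGraph
from nethub.synthetic_data import SynthConfig, build_bistable_fixture, generate_network


def complete_graph(n: int, costs: list[float] | None = None) -> UndirectedGraph:
    nodes = [chr(65 + i) for i in range(n)]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return UndirectedGraph(
        nodes, pairs, costs if costs is not None else [0.0] * len(pairs),
        weighted=costs is not None, name=f"K{n}",
    )


def cycle_graph(n: int, costs: list[float] | None = None) -> UndirectedGraph:
    nodes = [chr(65 + i) for i in range(n)]
    pairs = sorted((min(i, (i + 1) % n), max(i, (i + 1) % n)) for i in range(n))
    return UndirectedGraph(
        nodes, pairs, costs if costs is not None else [0.0] * n,
        weighted=costs is not None, name=f"C{n}",
    )


def path_graph(n: int) -> UndirectedGraph:
    nodes = [chr(97 + i) for i in range(n)]
    pairs = [(i, i + 1) for i in range(n - 1)]
    return UndirectedGraph(nodes, pairs, [0.0] * (n - 1), weighted=False, name=f"P{n}")


def star_graph(n_leaves: int) -> UndirectedGraph:
    nodes = ["hub"] + [f"leaf{i}" for i in range(n_leaves)]
    pairs = [(0, i + 1) for i in range(n_leaves)]
    return UndirectedGraph(nodes, pairs, [0.0] * n_leaves, weighted=False, name="star")


def random_connected_graph(seed: int, n_lo: int = 5, n_hi: int = 8):
    """Random sparse connected synthetic network + its undirected projection."""
    from nethub.graph_core import undirected_projection

    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    extra = int(rng.integers(1, 5))
    m = min(n - 1 + extra, n * (n - 1) // 2)
    cfg = SynthConfig(n_nodes=n, n_edges=m, planted_hub_count=1, seed=seed)
    net = generate_network(cfg)
    return net, undirected_projection(net)


@pytest.fixture(scope="session")
def bistable():
    """(network, rules, states) of the nine-node bistable fixture."""
    return build_bistable_fixture()
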