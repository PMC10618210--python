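"""Graph data model for TF interaction networks and spanning-tree primitives.

A regulatory network is held as a signed, directed, optionally weighted edge
list.  Structural (spanning-tree) analysis operates on the *undirected
projection*: directions and signs are dropped, antiparallel edges collapse to
one undirected edge, and each undirected edge carries a cost ``w = 1 - p``
where ``p`` is the interaction probability.  Distances between nodes are
integer hop counts (number of edges on the shortest path), never
cost-weighted.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Edge",
    "Network",
    "UndirectedGraph",
    "SpanningTree",
    "DisconnectedError",
    "InfeasibleSubsetError",
    "undirected_projection",
    "kruskal_decode",
    "tree_distance_matrix",
    "total_pairwise_distance",
    "total_edge_cost",
    "enumerate_spanning_trees",
]

ACTIVATING = "+"
INHIBITING = "-"
UNSIGNED = "?"
_SIGNS = {ACTIVATING, INHIBITING, UNSIGNED}


class DisconnectedError(ValueError):
    """The undirected projection of a network is not connected."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        parts = "; ".join("{" + ", ".join(c) + "}" for c in self.components)
        super().__init__(
            f"undirected projection is disconnected into "
            f"{len(self.components)} components: {parts}"
        )


class InfeasibleSubsetError(ValueError):
    """An edge subset does not induce a connected, vertex-covering subgraph."""


@dataclass(frozen=True)
class Edge:
    """One directed interaction.

    ``probability`` is the interaction probability ``p`` in [0, 1] (or None
    when the network is unweighted); the optimization cost is ``w = 1 - p``.
    """

    source: str
    target: str
    sign: str = UNSIGNED
    probability: float | None = None

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-loop on node {self.source!r}")
        if self.sign not in _SIGNS:
            raise ValueError(f"sign must be one of {sorted(_SIGNS)}, got {self.sign!r}")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def cost(self) -> float | None:
        return None if self.probability is None else 1.0 - self.probability


@dataclass
class Network:
    """A named, signed, directed TF network.

    ``nodes`` order is canonical: it defines the index order of binary state
    vectors used by the Boolean simulator.
    """

    nodes: list[str]
    edges: list[Edge]
    name: str = "network"

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("a network needs at least 2 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        known = set(self.nodes)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")
        seen = set()
        for e in self.edges:
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate directed edge {e.source}->{e.target}")
            seen.add(key)
        # connectivity of the undirected projection is a structural invariant
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        if not nx.is_connected(g):
            raise DisconnectedError(nx.connected_components(g))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, label: str) -> int:
        return self.nodes.index(label)

    def parents_of(self, node: str) -> list[str]:
        """Sources of edges targeting ``node``, in edge-list order."""
        return [e.source for e in self.edges if e.target == node]


@dataclass
class UndirectedGraph:
    """Undirected projection: node list plus deduplicated costed edge list.

    Edges are canonically ordered by sorted label pair; ``costs[i]`` is the
    Kruskal cost of edge ``i`` (0.0 for every edge in unweighted mode, which
    makes the decode tie-break purely on edge index).
    """

    nodes: list[str]
    edge_pairs: list[tuple[int, int]]  # node-index pairs, u < v
    costs: list[float]
    weighted: bool
    name: str = "graph"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_pairs)

    def edge_labels(self, i: int) -> tuple[str, str]:
        u, v = self.edge_pairs[i]
        return self.nodes[u], self.nodes[v]

    def incident_edges(self) -> list[list[int]]:
        inc: list[list[int]] = [[] for _ in self.nodes]
        for i, (u, v) in enumerate(self.edge_pairs):
            inc[u].append(i)
            inc[v].append(i)
        return inc

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, (u, v) in enumerate(self.edge_pairs):
            g.add_edge(self.nodes[u], self.nodes[v], cost=self.costs[i], index=i)
        return g


@dataclass(frozen=True)
class SpanningTree:
    """N-1 undirected edge indices spanning every node of the parent graph."""

    edge_indices: frozenset[int]
    graph: UndirectedGraph = field(compare=False, hash=False)

    def __post_init__(self):
        n = self.graph.n_nodes
        if len(self.edge_indices) != n - 1:
            raise ValueError(
                f"spanning tree needs {n - 1} edges, got {len(self.edge_indices)}"
            )
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in self.edge_indices:
            u, v = self.graph.edge_pairs[i]
            ru, rv = find(u), find(v)
            if ru == rv:
                raise ValueError("edge set contains a cycle")
            parent[ru] = rv
        # N-1 acyclic edges on N nodes are automatically spanning

    @property
    def signature(self) -> tuple[int, ...]:
        """Canonical identity of the tree: sorted edge indices."""
        return tuple(sorted(self.edge_indices))

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.graph.nodes]
        for i in self.edge_indices:
            u, v = self.graph.edge_pairs[i]
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degrees(self) -> list[int]:
        deg = [0] * self.graph.n_nodes
        for i in self.edge_indices:
            u, v = self.graph.edge_pairs[i]
            deg[u] += 1
            deg[v] += 1
        return deg


def undirected_projection(
    net: Network, merge: str = "max", name: str | None = None
) -> UndirectedGraph:
    """Drop directions and signs; collapse antiparallel edges.

    Parameters
    ----------
    net:
        The directed signed network.
    merge:
        How to combine the probabilities of a collapsed antiparallel pair:
        ``max`` (default; keeps the strongest evidence of interaction, i.e.
        the minimum cost), ``mean``, or ``min``.

    The network is *weighted* only if every directed edge carries a
    probability; otherwise all costs are 0 and Kruskal decoding tie-breaks
    purely on edge index.
    """
    if merge not in ("max", "mean", "min"):
        raise ValueError(f"merge must be max|mean|min, got {merge!r}")
    index = {label: i for i, label in enumerate(net.nodes)}
    probs: dict[tuple[int, int], list[float | None]] = {}
    for e in net.edges:
        # canonical orientation: lexicographically smaller label first
        u, v = sorted((index[e.source], index[e.target]), key=lambda i: net.nodes[i])
        probs.setdefault((u, v), []).append(e.probability)
    weighted = all(p is not None for ps in probs.values() for p in ps)
    # canonical edge order: sorted by node-label pair
    keys = sorted(probs, key=lambda k: (net.nodes[k[0]], net.nodes[k[1]]))
    costs = []
    for k in keys:
        if not weighted:
            costs.append(0.0)
            continue
        ps = probs[k]
        if merge == "max":
            p = max(ps)
        elif merge == "min":
            p = min(ps)
        else:
            p = sum(ps) / len(ps)
        costs.append(1.0 - p)
    g = UndirectedGraph(
        nodes=list(net.nodes),
        edge_pairs=keys,
        costs=costs,
        weighted=weighted,
        name=name or net.name,
    )
    _check_connected(g)
    return g


def _check_connected(g: UndirectedGraph) -> None:
    nxg = nx.Graph()
    nxg.add_nodes_from(range(g.n_nodes))
    nxg.add_edges_from(g.edge_pairs)
    if not nx.is_connected(nxg):
        comps = [[g.nodes[i] for i in c] for c in nx.connected_components(nxg)]
        raise DisconnectedError(comps)


def kruskal_order(graph: UndirectedGraph) -> list[int]:
    """Edge indices in ascending (cost, index) scan order."""
    return sorted(range(graph.n_edges), key=lambda i: (graph.costs[i], i))


def kruskal_decode(
    h: frozenset[int] | set[int],
    graph: UndirectedGraph,
    order: list[int] | None = None,
) -> SpanningTree:
    """Minimum spanning tree of the subgraph induced by the edge subset ``h``.

    Edges are scanned in ascending (cost, edge-index) order, so decoding is
    deterministic even under cost ties.  Raises :class:`InfeasibleSubsetError`
    when ``h`` does not connect all nodes (the GA treats that as a penalized
    value, never an archived one).
    """
    n = graph.n_nodes
    for i in h:
        if not 0 <= i < graph.n_edges:
            raise ValueError(f"edge index {i} out of range 0..{graph.n_edges - 1}")
    if order is None:
        order = kruskal_order(graph)
    parent = list(range(n))

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    chosen = []
    members = h if isinstance(h, (set, frozenset)) else set(h)
    for i in order:
        if i not in members:
            continue
        u, v = graph.edge_pairs[i]
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append(i)
            if len(chosen) == n - 1:
                break
    if len(chosen) != n - 1:
        raise InfeasibleSubsetError(
            f"edge subset spans only part of the graph ({len(chosen) + 1} of {n} nodes reachable)"
        )
    return SpanningTree(frozenset(chosen), graph)


def tree_distance_matrix(tree: SpanningTree) -> list[list[int]]:
    """Pairwise hop-count distances along the unique tree paths (BFS per node)."""
    n = tree.graph.n_nodes
    adj = tree.adjacency()
    dist = [[0] * n for _ in range(n)]
    for s in range(n):
        row = dist[s]
        seen = [False] * n
        seen[s] = True
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if not seen[y]:
                    seen[y] = True
                    row[y] = row[x] + 1
                    q.append(y)
    return dist


def total_pairwise_distance(tree: SpanningTree) -> int:
    """Sum of tree distances over all *ordered* node pairs i != j.

    The ordered-pair convention doubles the unordered sum; the argmin over
    trees is unchanged.
    """
    n = tree.graph.n_nodes
    adj = tree.adjacency()
    total = 0
    for s in range(n):
        depth = [-1] * n
        depth[s] = 0
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if depth[y] < 0:
                    depth[y] = depth[x] + 1
                    total += depth[y]
                    q.append(y)
    return total


def total_edge_cost(tree: SpanningTree) -> float:
    """Sum of edge costs w = 1 - p over the tree's edges."""
    g = tree.graph
    if not g.weighted:
        raise ValueError("graph is unweighted: edge costs are undefined")
    return sum(g.costs[i] for i in tree.edge_indices)


def enumerate_spanning_trees(
    graph: UndirectedGraph, max_nodes: int = 9, max_combinations: int = 3_000_000
) -> list[SpanningTree]:
    """Every spanning tree of ``graph``, exactly once (brute-force oracle).

    Filters all C(M, N-1) edge subsets through an acyclicity check, so it is
    only intended for small instances; the count can be verified against the
    Kirchhoff matrix-tree determinant.
    """
    n, m = graph.n_nodes, graph.n_edges
    if n > max_nodes:
        raise ValueError(
            f"{n} nodes exceeds max_nodes={max_nodes}; exhaustive enumeration "
            "is only for small oracle instances — use the GA search instead"
        )
    import math

    if math.comb(m, n - 1) > max_combinations:
        raise ValueError(
            f"C({m}, {n - 1}) candidate subsets exceed {max_combinations}"
        )
    trees = []
    pairs = graph.edge_pairs
    for combo in itertools.combinations(range(m), n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i in combo:
            u, v = pairs[i]
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            trees.append(SpanningTree(frozenset(combo), graph))
    return trees


def spanning_tree_count_kirchhoff(graph: UndirectedGraph) -> int:
    """Number of spanning trees via the matrix-tree theorem (determinant of a
    Laplacian minor); independent cross-check for the enumerator."""
    import numpy as np

    n = graph.n_nodes
    lap = np.zeros((n, n))
    for u, v in graph.edge_pairs:
        lap[u, u] += 1
        lap[v, v] += 1
        lap[u, v] -= 1
        lap[v, u] -= 1
    sign, logdet = np.linalg.slogdet(lap[1:, 1:])
    if sign <= 0:
        return 0
    return int(round(sign * np.exp(logdet)))
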