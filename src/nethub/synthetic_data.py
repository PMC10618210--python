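"""Generators that emulate the study inputs at desk scale.

Three kinds of object are produced, mirroring what a TF-network structural
analysis consumes: (i) random connected signed directed networks with planted
hubs and Beta-distributed interaction probabilities, sized like real curated
TF networks (default 35 nodes / 239 interactions); (ii) threshold-with-noise
probabilistic Boolean rule tables; and (iii) a hand-specified nine-node
bistable fixture with two named attractor states joined by a hub-connecting
pathway, small enough that its state space and spanning-tree set can be
checked exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolean_sim import NetworkState, RuleTable
from .graph_core import ACTIVATING, INHIBITING, Edge, Network

__all__ = [
    "SynthConfig",
    "generate_network",
    "generate_threshold_rules",
    "build_bistable_fixture",
    "find_fixed_points",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the random-network generator.

    Defaults size the output like a curated TF network: 35 nodes and 239
    signed directed interactions, with two planted hubs that receive a strong
    share of the extra edges.
    """

    n_nodes: int = 35
    n_edges: int = 239
    planted_hub_count: int = 2
    hub_boost: float = 0.6  # probability an extra edge touches a planted hub
    activator_fraction: float = 0.5
    rule_noise: float = 0.05  # epsilon of the threshold rules
    beta_a: float = 2.0  # edge probability ~ Beta(a, b) scaled to [p_lo, p_hi]
    beta_b: float = 2.0
    p_lo: float = 0.05
    p_hi: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("n_edges must be at least n_nodes - 1")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("too many edges for distinct directed pairs")
        if not 0.0 <= self.activator_fraction <= 1.0:
            raise ValueError("activator_fraction must be in [0, 1]")
        if not 0.0 <= self.rule_noise < 0.5:
            raise ValueError("rule_noise must be in [0, 0.5)")
        if not 0.0 <= self.hub_boost <= 1.0:
            raise ValueError("hub_boost must be in [0, 1]")


def _node_labels(n: int) -> list[str]:
    return [f"TF{i:02d}" for i in range(n)]


def generate_network(cfg: SynthConfig) -> Network:
    """Random connected signed directed network with planted hubs.

    A random tree backbone (random attachment over a shuffled node order)
    guarantees connectivity of the undirected projection; extra directed
    edges are then added, each touching a planted hub with probability
    ``hub_boost``.  Every edge gets a sign and an interaction probability
    drawn from the configured scaled Beta distribution.  Deterministic per
    (cfg, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _node_labels(cfg.n_nodes)
    order = list(rng.permutation(cfg.n_nodes))
    hubs = [labels[i] for i in order[: cfg.planted_hub_count]]

    pairs: set[tuple[int, int]] = set()
    edges_idx: list[tuple[int, int]] = []

    def add_pair(u: int, v: int) -> bool:
        if u == v or (u, v) in pairs:
            return False
        pairs.add((u, v))
        edges_idx.append((u, v))
        return True

    # backbone: attach each node to a random earlier node, random orientation
    for pos in range(1, cfg.n_nodes):
        u = order[pos]
        v = order[int(rng.integers(pos))]
        if rng.random() < 0.5:
            add_pair(u, v)
        else:
            add_pair(v, u)

    hub_idx = [labels.index(h) for h in hubs]
    while len(edges_idx) < cfg.n_edges:
        if hub_idx and rng.random() < cfg.hub_boost:
            a = hub_idx[int(rng.integers(len(hub_idx)))]
            b = int(rng.integers(cfg.n_nodes))
            if rng.random() < 0.5:
                add_pair(a, b)
            else:
                add_pair(b, a)
        else:
            add_pair(int(rng.integers(cfg.n_nodes)), int(rng.integers(cfg.n_nodes)))

    signs = rng.random(len(edges_idx)) < cfg.activator_fraction
    probs = cfg.p_lo + (cfg.p_hi - cfg.p_lo) * rng.beta(
        cfg.beta_a, cfg.beta_b, size=len(edges_idx)
    )
    edges = [
        Edge(
            labels[u],
            labels[v],
            ACTIVATING if s else INHIBITING,
            float(p),
        )
        for (u, v), s, p in zip(edges_idx, signs, probs)
    ]
    net = Network(labels, edges, name=f"synthetic-n{cfg.n_nodes}-m{cfg.n_edges}")
    net.planted_hubs = hubs  # annotation for recovery studies
    return net


def generate_threshold_rules(
    net: Network, epsilon: float = 0.05, seed: int = 0, max_parents: int = 12
) -> RuleTable:
    """Threshold-with-noise rule tables for every node of ``net``.

    For each parent configuration the net input is (#active activators -
    #active inhibitors): P(ON) is 1 - epsilon when positive, epsilon when
    negative, and 0.5 on a tie (ties create genuine stochastic wandering).
    Parentless nodes get a single basal probability of 0.5.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    sign_of = {(e.source, e.target): e.sign for e in net.edges}
    for node in net.nodes:
        plist = tuple(net.parents_of(node))
        k = len(plist)
        if k > max_parents:
            raise ValueError(
                f"node {node!r} has {k} parents; 2^{k} rule rows is too large "
                f"(max_parents={max_parents})"
            )
        parents[node] = plist
        table = np.empty(2**k)
        for row in range(2**k):
            net_input = 0
            for j, p in enumerate(plist):
                bit = (row >> (k - 1 - j)) & 1
                if not bit:
                    continue
                net_input += 1 if sign_of[(p, node)] == ACTIVATING else -1
            if net_input > 0:
                table[row] = 1.0 - epsilon
            elif net_input < 0:
                table[row] = epsilon
            else:
                table[row] = 0.5
        tables[node] = table
    return RuleTable(list(net.nodes), parents, tables)


# --- bistable fixture ------------------------------------------------------

_FIXTURE_EPS = 0.001


def build_bistable_fixture() -> tuple[Network, RuleTable, dict[str, NetworkState]]:
    """Nine-node bistable system with two attractors joined by a hub pathway.

    Two mutually inhibiting modules: an "NE-like" module around hub H1
    (members A1..A3) and a "NON-NE-like" module around hub H2 (members
    B1..B3), joined by bridge node BR on the pathway H1-BR-H2.  With
    threshold rules at a low noise level (epsilon=0.001, chosen so that at
    this small scale coordinated noise flips do not erode the basins within a
    typical run), deterministic rounding of the lookup probabilities has
    exactly two fixed points — NE_like (H1 module + BR ON)
    and NONNE_like (H2 module ON) — verified here by exhaustive scan over all
    2^9 states.  Clamping H1 and BR ON destabilizes NONNE_like, which is the
    pathway-activation experiment the simulator reproduces.
    """
    a = ACTIVATING
    i = INHIBITING
    nodes = ["H1", "A1", "A2", "A3", "H2", "B1", "B2", "B3", "BR"]
    # Design notes, in terms of each node's net input (#active activators -
    # #active inhibitors):
    # * Every module member has two activators (its hub + a module ring) and
    #   two inhibitors (the rival hub + one rival member), so in either
    #   attractor all inputs sit at +/-2 and any single noise flip leaves
    #   them strictly signed: both basins are deep.
    # * H2 has exactly two activators (B1, B2) and two inhibitors (H1, BR):
    #   clamping H1 and BR ON turns its rule row into the 0.5 tie, and with
    #   H1 ON the B members fall to a tie once H2 drops — the
    #   pathway-activation experiment dismantles NONNE_like node by node.
    # * Both hubs are adjacent to every other node in the undirected
    #   projection, so the dense-tree optimum is attained exactly by the two
    #   hub-centered stars (the only trees of diameter 2).
    edges = [
        # NE-like module around hub H1 (members A1..A3 in an activation ring)
        Edge("A1", "H1", a), Edge("A2", "H1", a), Edge("A3", "H1", a),
        Edge("H2", "H1", i), Edge("B1", "H1", i),
        Edge("H1", "A1", a), Edge("A2", "A1", a),
        Edge("H2", "A1", i), Edge("B1", "A1", i),
        Edge("H1", "A2", a), Edge("A3", "A2", a),
        Edge("H2", "A2", i), Edge("B2", "A2", i),
        Edge("H1", "A3", a), Edge("A1", "A3", a),
        Edge("H2", "A3", i), Edge("B3", "A3", i),
        # NON-NE-like module around hub H2
        Edge("B1", "H2", a), Edge("B2", "H2", a),
        Edge("H1", "H2", i), Edge("BR", "H2", i),
        Edge("H2", "B1", a), Edge("B2", "B1", a),
        Edge("H1", "B1", i), Edge("A1", "B1", i),
        Edge("H2", "B2", a), Edge("B3", "B2", a),
        Edge("H1", "B2", i), Edge("A2", "B2", i),
        Edge("H2", "B3", a), Edge("B1", "B3", a),
        Edge("H1", "B3", i), Edge("A3", "B3", i),
        # bridge pathway H1 -> BR -| H2
        Edge("H1", "BR", a), Edge("H2", "BR", i),
    ]
    net = Network(nodes, edges, name="bistable-fixture")
    rules = generate_threshold_rules(net, epsilon=_FIXTURE_EPS)
    ne = NetworkState.from_dict(
        nodes,
        {"H1": 1, "A1": 1, "A2": 1, "A3": 1,
         "H2": 0, "B1": 0, "B2": 0, "B3": 0, "BR": 1},
    )
    nonne = NetworkState.from_dict(
        nodes,
        {"H1": 0, "A1": 0, "A2": 0, "A3": 0,
         "H2": 1, "B1": 1, "B2": 1, "B3": 1, "BR": 0},
    )
    fixed = find_fixed_points(rules)
    expected = {tuple(ne.bits.tolist()), tuple(nonne.bits.tolist())}
    found = {tuple(s.bits.tolist()) for s in fixed}
    if found != expected:
        raise AssertionError(
            f"fixture must have exactly the two named fixed points; found {found}"
        )
    return net, rules, {"NE_like": ne, "NONNE_like": nonne}


def find_fixed_points(rules: RuleTable, max_nodes: int = 16) -> list[NetworkState]:
    """All states reproduced by deterministic rounding of the lookup rules.

    A state is fixed when every node's lookup probability rounds back to its
    current bit (> 0.5 -> 1, < 0.5 -> 0); a probability of exactly 0.5 is
    treated as unstable, so such states are never fixed.  Exhaustive over all
    2^N states.
    """
    n = rules.n_nodes
    if n > max_nodes:
        raise ValueError(
            f"{n} nodes exceeds max_nodes={max_nodes}; exhaustive fixed-point "
            "scan is only for small systems"
        )
    nodes = rules.nodes
    out = []
    for code in range(2**n):
        bits = np.array([(code >> (n - 1 - j)) & 1 for j in range(n)], dtype=np.int8)
        state = NetworkState(list(nodes), bits)
        ok = True
        for node in nodes:
            p = rules.p_on[node][rules.row_index(node, state)]
            if p == 0.5:
                ok = False
                break
            rounded = 1 if p > 0.5 else 0
            if rounded != bits[state.index[node]]:
                ok = False
                break
        if ok:
            out.append(state)
    return out
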