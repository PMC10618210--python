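"""Probabilistic Boolean network simulator with general asynchronous updates.

Each node carries a lookup table giving its probability of being ON for every
combination of its parents' states.  One iteration updates a single node: a
node is drawn uniformly from the non-clamped nodes, its ON-probability is
fetched from the table at the parents' instantaneous states, and a weighted
coin sets its new state.  Clamped nodes are forced permanently ON or OFF (a
pathway-activation experiment); they are excluded from the draw, which leaves
the marginal dynamics of the free nodes unchanged while wasting no
iterations.

The module also derives interaction probabilities from rule tables: the
influence of a parent on a child is the difference of the child's conditional
ON-probabilities with the parent ON versus OFF, averaged uniformly over the
other parents' configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_core import Network

__all__ = [
    "RuleTable",
    "NetworkState",
    "ClampSpec",
    "Trajectory",
    "EnsembleSummary",
    "lookup_probability",
    "async_step",
    "run_transition",
    "run_ensemble",
    "edge_probability_from_rules",
]


@dataclass
class RuleTable:
    """Per-node probabilistic Boolean rules.

    ``parents[node]`` is the ordered parent list; ``p_on[node]`` has one row
    per parent-state combination in binary counting order over the parent
    list (first parent = most significant bit: rows 00, 01, 10, 11 for two
    parents).  A parentless node carries a single basal probability.
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    p_on: dict[str, np.ndarray]

    def __post_init__(self):
        known = set(self.nodes)
        for node in self.nodes:
            if node not in self.parents or node not in self.p_on:
                raise ValueError(f"missing rule for node {node!r}")
            for p in self.parents[node]:
                if p not in known:
                    raise ValueError(f"rule for {node!r} references unknown parent {p!r}")
            table = np.asarray(self.p_on[node], dtype=float)
            k = len(self.parents[node])
            if table.shape != (2**k,):
                raise ValueError(
                    f"rule table for {node!r} needs {2**k} rows, got {table.shape}"
                )
            if np.any((table < 0) | (table > 1)):
                raise ValueError(f"rule table for {node!r} has probabilities outside [0,1]")
            self.p_on[node] = table

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def row_index(self, node: str, state: "NetworkState") -> int:
        idx = 0
        for p in self.parents[node]:
            idx = (idx << 1) | int(state.bits[state.index[p]])
        return idx


@dataclass
class NetworkState:
    """Binary TF state vector over a fixed node order."""

    nodes: list[str]
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.nodes),):
            raise ValueError("state length does not match node list")
        if np.any((self.bits != 0) & (self.bits != 1)):
            raise ValueError("state entries must be 0 or 1")
        self.index = {n: i for i, n in enumerate(self.nodes)}

    @classmethod
    def from_dict(cls, nodes: list[str], mapping: dict[str, int]) -> "NetworkState":
        missing = [n for n in nodes if n not in mapping]
        if missing:
            raise ValueError(f"state is missing nodes: {missing}")
        return cls(list(nodes), np.array([mapping[n] for n in nodes]))

    def to_dict(self) -> dict[str, int]:
        return {n: int(b) for n, b in zip(self.nodes, self.bits)}

    def copy(self) -> "NetworkState":
        return NetworkState(list(self.nodes), self.bits.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NetworkState)
            and self.nodes == other.nodes
            and bool(np.array_equal(self.bits, other.bits))
        )


@dataclass(frozen=True)
class ClampSpec:
    """Nodes forced permanently ON or OFF during a simulation."""

    force_on: frozenset[str] = frozenset()
    force_off: frozenset[str] = frozenset()

    def __post_init__(self):
        overlap = self.force_on & self.force_off
        if overlap:
            raise ValueError(f"nodes clamped both ON and OFF: {sorted(overlap)}")

    @classmethod
    def of(cls, on=(), off=()) -> "ClampSpec":
        return cls(frozenset(on), frozenset(off))

    @property
    def clamped(self) -> frozenset[str]:
        return self.force_on | self.force_off

    def validate(self, nodes: list[str]) -> None:
        unknown = self.clamped - set(nodes)
        if unknown:
            raise ValueError(f"clamp references unknown nodes: {sorted(unknown)}")

    def apply(self, state: NetworkState) -> NetworkState:
        out = state.copy()
        for n in self.force_on:
            out.bits[out.index[n]] = 1
        for n in self.force_off:
            out.bits[out.index[n]] = 0
        return out


@dataclass
class Trajectory:
    """Per-iteration log of one asynchronous transition run.

    ``updated_nodes[t]`` and ``new_bits[t]`` record iteration t (0-based); the
    full state sequence is reconstructible by replay from ``initial``.
    """

    initial: NetworkState
    updated_nodes: list[int]  # node indices
    new_bits: list[int]
    converged: bool
    iterations: int
    seed: int
    final: NetworkState = field(repr=False, default=None)

    def replay(self):
        """Yield (iteration, node_index, state) after every update."""
        state = self.initial.copy()
        for t, (i, b) in enumerate(zip(self.updated_nodes, self.new_bits)):
            state.bits[i] = b
            yield t, i, state


def lookup_probability(rules: RuleTable, node: str, state: NetworkState) -> float:
    """Probability the node turns ON given its parents' instantaneous states."""
    if node not in rules.parents:
        raise ValueError(f"no rule for node {node!r}")
    if len(state.nodes) != rules.n_nodes:
        raise ValueError("state length does not match rule table")
    return float(rules.p_on[node][rules.row_index(node, state)])


def async_step(
    state: NetworkState,
    rules: RuleTable,
    clamp: ClampSpec,
    rng: np.random.Generator,
    free_indices: np.ndarray | None = None,
) -> tuple[NetworkState, str]:
    """One general-asynchronous update; returns the new state and the node drawn."""
    if free_indices is None:
        free = [i for i, n in enumerate(state.nodes) if n not in clamp.clamped]
        free_indices = np.array(free, dtype=int)
    if free_indices.size == 0:
        raise ValueError("all nodes are clamped; nothing to update")
    i = int(free_indices[rng.integers(free_indices.size)])
    node = state.nodes[i]
    p = lookup_probability(rules, node, state)
    new = state.copy()
    new.bits[i] = 1 if rng.random() < p else 0
    return new, node


def run_transition(
    rules: RuleTable,
    init: NetworkState,
    target: NetworkState | list[NetworkState],
    clamp: ClampSpec = ClampSpec(),
    max_iter: int = 1_000_000,
    seed: int = 0,
) -> Trajectory:
    """Iterate asynchronous updates until the state reaches a target or the
    iteration cap.

    ``target`` may be a single state or a list of equivalent target states
    (e.g. several variants of the same phenotype); the run converges on
    reaching any member.  Clamps are applied to the initial state before the
    first iteration.  A target that violates the clamp triggers a warning —
    the run still executes but cannot converge to that member.
    """
    targets = target if isinstance(target, list) else [target]
    clamp.validate(init.nodes)
    for tgt in targets:
        if len(tgt.nodes) != len(init.nodes):
            raise ValueError("init/target lengths do not match")
        clamped_tgt = clamp.apply(tgt)
        if clamped_tgt != tgt:
            warnings.warn(
                "target state violates the clamp; the run cannot converge to it",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    state = clamp.apply(init)
    free = np.array(
        [i for i, n in enumerate(state.nodes) if n not in clamp.clamped], dtype=int
    )
    if free.size == 0:
        raise ValueError("all nodes are clamped; nothing to update")

    target_bits = [np.asarray(t.bits) for t in targets]

    def at_target(bits) -> bool:
        return any(np.array_equal(bits, tb) for tb in target_bits)

    updated: list[int] = []
    new_bits: list[int] = []
    converged = at_target(state.bits)
    bits = state.bits  # updated in place; copies only at the boundaries
    it = 0
    while not converged and it < max_iter:
        i = int(free[rng.integers(free.size)])
        node = state.nodes[i]
        row = 0
        for p in rules.parents[node]:
            row = (row << 1) | int(bits[state.index[p]])
        prob = rules.p_on[node][row]
        bits[i] = 1 if rng.random() < prob else 0
        updated.append(i)
        new_bits.append(int(bits[i]))
        it += 1
        converged = at_target(bits)
    final = NetworkState(list(state.nodes), bits.copy())
    return Trajectory(
        initial=clamp.apply(init),
        updated_nodes=updated,
        new_bits=new_bits,
        converged=converged,
        iterations=it,
        seed=seed,
        final=final,
    )


@dataclass
class EnsembleSummary:
    n_runs: int
    n_converged: int
    iteration_quantiles: dict[str, float]  # over converged runs; empty if none

    @property
    def convergence_fraction(self) -> float:
        return self.n_converged / self.n_runs


def run_ensemble(
    rules: RuleTable,
    init: NetworkState,
    target: NetworkState | list[NetworkState],
    clamp: ClampSpec = ClampSpec(),
    n_runs: int = 700,
    max_iter: int = 1_000_000,
    base_seed: int = 0,
) -> tuple[list[Trajectory], EnsembleSummary]:
    """Independent seeded transition runs (seed = base_seed + run index)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    trajectories = [
        run_transition(rules, init, target, clamp, max_iter, base_seed + r)
        for r in range(n_runs)
    ]
    iters = [t.iterations for t in trajectories if t.converged]
    quantiles = {}
    if iters:
        qs = np.quantile(iters, [0.25, 0.5, 0.75])
        quantiles = {"q25": float(qs[0]), "median": float(qs[1]), "q75": float(qs[2])}
    summary = EnsembleSummary(
        n_runs=n_runs, n_converged=len(iters), iteration_quantiles=quantiles
    )
    return trajectories, summary


def edge_probability_from_rules(
    rules: RuleTable, parent: str, child: str
) -> tuple[float, float, float]:
    """Interaction probability of an edge from a child's rule table.

    The influence of ``parent`` on ``child`` is the child's conditional
    ON-probability with the parent ON minus with the parent OFF, averaged
    uniformly over all configurations of the child's other parents.  An
    inhibitory parent yields a negative difference; the returned probability
    is its absolute value so that the cost w = 1 - p stays in [0, 1], and the
    signed value is reported alongside.

    Returns ``(p, w, signed_delta)``.
    """
    if child not in rules.parents:
        raise ValueError(f"no rule for node {child!r}")
    parents = rules.parents[child]
    if parent not in parents:
        raise ValueError(f"{parent!r} is not a regulator of {child!r}")
    k = len(parents)
    pos = parents.index(parent)
    shift = k - 1 - pos  # bit position of `parent` in the row index
    table = rules.p_on[child]
    deltas = []
    for cfg in range(2 ** (k - 1)):
        low = cfg & ((1 << shift) - 1)
        high = (cfg >> shift) << (shift + 1)
        row_off = high | low
        row_on = row_off | (1 << shift)
        deltas.append(table[row_on] - table[row_off])
    signed = float(np.mean(deltas))
    p = abs(signed)
    return p, 1.0 - p, signed


def network_from_rules(rules: RuleTable, name: str = "rules-network") -> Network:
    """Directed network whose edge probabilities are derived from the rules."""
    from .graph_core import Edge

    edges = []
    for child in rules.nodes:
        for parent in rules.parents[child]:
            p, _w, signed = edge_probability_from_rules(rules, parent, child)
            sign = "+" if signed > 0 else ("-" if signed < 0 else "?")
            edges.append(Edge(parent, child, sign, p))
    return Network(list(rules.nodes), edges, name=name)
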