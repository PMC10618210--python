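"""Genetic-algorithm search for dense spanning trees (DST) and minimum dense
spanning trees (MDST).

A *dense spanning tree* minimizes the total pairwise hop distance between all
node pairs; it concentrates connectivity into hubs.  The *minimum dense
spanning tree* additionally minimizes the total edge cost w = 1 - p, so the
tree keeps the most probable interactions while staying dense.

The chromosome is a set of distinct undirected edge indices (at least one
edge adjacent to every vertex); a candidate is decoded to a tree by running
Kruskal on the induced subgraph.  Because many distinct chromosomes decode to
the same optimal tree, the search keeps an archive of every distinct decoded
tree that ties the best objective seen so far; the archive is a lower bound
on the true co-optimal set, which is why a brute-force enumeration oracle is
provided alongside for small instances.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .graph_core import (
    InfeasibleSubsetError,
    SpanningTree,
    UndirectedGraph,
    enumerate_spanning_trees,
    kruskal_decode,
    kruskal_order,
    total_edge_cost,
    total_pairwise_distance,
)

__all__ = [
    "GAConfig",
    "ObjectiveValue",
    "TreeArchive",
    "fitness",
    "compare",
    "ga_search",
    "brute_force_search",
]

DST = "DST"
MDST = "MDST"

COST_TOL = 1e-9  # absolute tolerance for cost ties in the MDST archive


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05  # per gene
    chromosome_length: int | None = None  # default N-1 (tree-sized)
    restarts: int = 10
    seed: int = 0
    infeasible_penalty: float = 1e6  # added per uncovered vertex / component
    patience: int = 30  # generations without improvement or new archive member
    tournament_size: int = 3
    scalarization: str = "lex"  # MDST ordering: "lex" or "weighted"
    weight_lambda: float = 1.0  # weighted-sum lambda

    def __post_init__(self):
        for name in ("population_size", "generations", "restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.scalarization not in ("lex", "weighted"):
            raise ValueError("scalarization must be 'lex' or 'weighted'")

    def resolved_length(self, graph: UndirectedGraph) -> int:
        # Tree-sized chromosomes: a connected chromosome Kruskal-decodes to
        # itself, so every spanning tree is representable.  Longer
        # chromosomes are allowed but the index-ordered decode then biases
        # which trees are reachable.
        n, m = graph.n_nodes, graph.n_edges
        length = self.chromosome_length
        if length is None:
            length = n - 1
        if not n - 1 <= length <= m:
            raise ValueError(
                f"chromosome_length must be in [{n - 1}, {m}], got {length}"
            )
        return length


@dataclass(frozen=True)
class ObjectiveValue:
    """The minimands: total ordered-pair distance, and (MDST only) total cost."""

    distance_total: int
    cost_total: float | None = None

    def __post_init__(self):
        if self.distance_total <= 0:
            raise ValueError("distance_total must be positive")
        if self.cost_total is not None and self.cost_total < -COST_TOL:
            raise ValueError("cost_total must be non-negative")


def compare(
    a: ObjectiveValue,
    b: ObjectiveValue,
    mode: str,
    scalarization: str = "lex",
    weight_lambda: float = 1.0,
) -> int:
    """-1 if a is better (smaller), +1 if b is, 0 on a tie.

    DST compares distance only.  MDST defaults to lexicographic
    (distance first, then cost with absolute tolerance 1e-9); a weighted-sum
    scalarization distance + lambda*cost is selectable for sensitivity
    analysis.
    """
    if mode == DST:
        if (a.cost_total is None) != (b.cost_total is None):
            raise ValueError("cannot compare values from different modes")
        return (a.distance_total > b.distance_total) - (
            a.distance_total < b.distance_total
        )
    if mode != MDST:
        raise ValueError(f"unknown mode {mode!r}")
    if a.cost_total is None or b.cost_total is None:
        raise ValueError("MDST comparison requires cost_total on both values")
    if scalarization == "weighted":
        sa = a.distance_total + weight_lambda * a.cost_total
        sb = b.distance_total + weight_lambda * b.cost_total
        if abs(sa - sb) <= COST_TOL:
            return 0
        return -1 if sa < sb else 1
    if a.distance_total != b.distance_total:
        return -1 if a.distance_total < b.distance_total else 1
    if abs(a.cost_total - b.cost_total) <= COST_TOL:
        return 0
    return -1 if a.cost_total < b.cost_total else 1


@dataclass
class TreeArchive:
    """All distinct trees found to attain the optimum objective of a search."""

    mode: str
    optimum: ObjectiveValue
    trees: dict[tuple[int, ...], SpanningTree] = field(default_factory=dict)
    evaluations: int = 0

    def __len__(self) -> int:
        return len(self.trees)

    def signatures(self) -> set[tuple[int, ...]]:
        return set(self.trees)

    def add(self, tree: SpanningTree) -> bool:
        sig = tree.signature
        if sig in self.trees:
            return False
        self.trees[sig] = tree
        return True


def evaluate_tree(tree: SpanningTree, mode: str) -> ObjectiveValue:
    dist = total_pairwise_distance(tree)
    if mode == DST:
        return ObjectiveValue(dist)
    return ObjectiveValue(dist, total_edge_cost(tree))


def fitness(
    h: frozenset[int] | set[int],
    graph: UndirectedGraph,
    mode: str = DST,
    config: GAConfig | None = None,
    order: list[int] | None = None,
) -> tuple[ObjectiveValue | None, SpanningTree | None, float]:
    """Decode a chromosome and score it.

    Returns ``(objective, tree, penalty)``.  Infeasible chromosomes (uncovered
    vertex, or induced subgraph disconnected) yield ``(None, None, penalty)``
    where the penalty grows with the number of uncovered vertices — a value
    the selection can rank, never an exception and never archived.
    """
    config = config or GAConfig()
    covered = set()
    for i in h:
        u, v = graph.edge_pairs[i]
        covered.add(u)
        covered.add(v)
    uncovered = graph.n_nodes - len(covered)
    if uncovered:
        return None, None, config.infeasible_penalty * (1 + uncovered)
    try:
        tree = kruskal_decode(h, graph, order=order)
    except InfeasibleSubsetError:
        return None, None, config.infeasible_penalty
    return evaluate_tree(tree, mode), tree, 0.0


def _selection_key(
    obj: ObjectiveValue | None, penalty: float, mode: str, config: GAConfig
) -> tuple:
    if obj is None:
        return (1, penalty, 0.0)
    if mode == DST:
        return (0, obj.distance_total, 0.0)
    if config.scalarization == "weighted":
        return (0, obj.distance_total + config.weight_lambda * obj.cost_total, 0.0)
    return (0, obj.distance_total, obj.cost_total)


def _repair(
    genes: set[int], length: int, graph: UndirectedGraph,
    incident: list[list[int]], rng: random.Random,
) -> set[int]:
    """Make a gene set feasible: exactly ``length`` distinct indices whose
    induced subgraph spans and connects all vertices.

    A union-find pass over the genes (random order) splits them into a
    spanning forest and cycle-closing extras; random component-crossing
    edges are swapped in until the forest spans, then the length is adjusted
    by dropping cycle extras or padding with random edges."""
    n, m = graph.n_nodes, graph.n_edges
    pairs = graph.edge_pairs
    while len(genes) < length:
        genes.add(rng.randrange(m))

    def forest_split(gs):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        tree, extra = [], []
        order = list(gs)
        rng.shuffle(order)
        for i in order:
            u, v = pairs[i]
            ru, rv = find(u), find(v)
            if ru == rv:
                extra.append(i)
            else:
                parent[ru] = rv
                tree.append(i)
        comp = {}
        labels = [0] * n
        for x in range(n):
            labels[x] = comp.setdefault(find(x), len(comp))
        return tree, extra, labels

    tree, extra, labels = forest_split(genes)
    while len(tree) < n - 1:
        crossing = [
            i for i in range(m)
            if i not in genes and labels[pairs[i][0]] != labels[pairs[i][1]]
        ]
        genes.add(rng.choice(crossing))
        tree, extra, labels = forest_split(genes)
    while len(genes) > length and extra:
        drop = extra.pop(rng.randrange(len(extra)))
        genes.discard(drop)
    while len(genes) < length:
        genes.add(rng.randrange(m))
    return genes


def ga_search(
    graph: UndirectedGraph, mode: str = DST, config: GAConfig | None = None
) -> TreeArchive:
    """Search for the co-optimal tree set with a restarted genetic algorithm.

    Each restart runs tournament selection, uniform crossover over index sets
    (duplicate genes repaired), per-gene index-replacement mutation, and
    elitism of one.  Every feasible decoded tree tying the best-ever objective
    (under the mode's comparison) is archived; the archive resets whenever a
    strictly better value appears.  Deterministic for a fixed
    (graph, config, seed).
    """
    config = config or GAConfig()
    if mode == MDST and not graph.weighted:
        raise ValueError("MDST mode requires edge probabilities on the graph")
    if mode not in (DST, MDST):
        raise ValueError(f"unknown mode {mode!r}")
    length = config.resolved_length(graph)
    m = graph.n_edges
    order = kruskal_order(graph)
    incident = graph.incident_edges()
    rng = random.Random(config.seed)

    archive: TreeArchive | None = None
    best_obj: ObjectiveValue | None = None
    evaluations = 0
    # memoize decode+score per chromosome signature: mutation revisits often
    cache: dict[frozenset[int], tuple] = {}

    def score(genes: frozenset[int]):
        nonlocal evaluations
        hit = cache.get(genes)
        if hit is None:
            evaluations += 1
            hit = fitness(genes, graph, mode, config, order=order)
            cache[genes] = hit
        return hit

    def consider(obj: ObjectiveValue | None, tree: SpanningTree | None) -> bool:
        """Archive maintenance; returns True when the archive changed."""
        nonlocal archive, best_obj
        if obj is None:
            return False
        if best_obj is None or compare(
            obj, best_obj, mode, config.scalarization, config.weight_lambda
        ) < 0:
            best_obj = obj
            archive = TreeArchive(mode=mode, optimum=obj)
            archive.add(tree)
            return True
        if compare(obj, best_obj, mode, config.scalarization, config.weight_lambda) == 0:
            return archive.add(tree)
        return False

    for _ in range(config.restarts):
        pop: list[frozenset[int]] = []
        for _ in range(config.population_size):
            genes = set(rng.sample(range(m), length))
            genes = _repair(genes, length, graph, incident, rng)
            pop.append(frozenset(genes))
        if all(score(ind)[0] is None for ind in pop):
            raise RuntimeError("no feasible individual after initialization repair")

        stale = 0
        for _gen in range(config.generations):
            changed = False
            scored = []
            for ind in pop:
                obj, tree, pen = score(ind)
                if consider(obj, tree):
                    changed = True
                scored.append((ind, _selection_key(obj, pen, mode, config)))
            scored.sort(key=lambda t: t[1])
            elite = scored[0][0]

            def tournament() -> frozenset[int]:
                picks = [scored[rng.randrange(len(scored))] for _ in range(config.tournament_size)]
                return min(picks, key=lambda t: t[1])[0]

            nxt = [elite]
            while len(nxt) < config.population_size:
                p1, p2 = tournament(), tournament()
                if rng.random() < config.crossover_rate:
                    common = p1 & p2
                    pool = list((p1 | p2) - common)
                    rng.shuffle(pool)
                    child = set(common)
                    for g in pool:
                        if len(child) >= length:
                            break
                        if rng.random() < 0.5:
                            child.add(g)
                    for g in pool:
                        if len(child) >= length:
                            break
                        child.add(g)
                else:
                    child = set(p1)
                # per-gene index-replacement mutation
                for g in list(child):
                    if rng.random() < config.mutation_rate:
                        child.discard(g)
                        child.add(rng.randrange(m))
                child = _repair(child, length, graph, incident, rng)
                nxt.append(frozenset(child))
            pop = nxt
            stale = 0 if changed else stale + 1
            if config.patience and stale >= config.patience:
                break

    if archive is None:
        raise RuntimeError("search produced no feasible spanning tree")
    archive.evaluations = evaluations
    return archive


def brute_force_search(
    graph: UndirectedGraph, mode: str = DST, max_nodes: int = 9,
    scalarization: str = "lex", weight_lambda: float = 1.0,
) -> TreeArchive:
    """Exhaustive oracle: score every spanning tree, archive all optima."""
    if mode == MDST and not graph.weighted:
        raise ValueError("MDST mode requires edge probabilities on the graph")
    trees = enumerate_spanning_trees(graph, max_nodes=max_nodes)
    archive: TreeArchive | None = None
    best: ObjectiveValue | None = None
    for tree in trees:
        obj = evaluate_tree(tree, mode)
        if best is None or compare(obj, best, mode, scalarization, weight_lambda) < 0:
            best = obj
            archive = TreeArchive(mode=mode, optimum=obj)
            archive.add(tree)
        elif compare(obj, best, mode, scalarization, weight_lambda) == 0:
            archive.add(tree)
    if archive is None:
        raise RuntimeError("graph has no spanning tree")
    archive.evaluations = len(trees)
    return archive
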