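"""Hub statistics over archives of co-optimal spanning trees.

A hub is a node whose number of connections sits above the average.  Because
the co-optimal tree set is usually large and different trees highlight
different nodes, hubs are called on the *mean degree across the whole
archive*: a node that is consistently central in the dense trees has a high
mean degree, while nodes that are hubs in only a few trees wash out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .dst_search import TreeArchive
from .graph_core import Network, undirected_projection

__all__ = ["HubReport", "average_degrees", "identify_hubs", "hub_connecting_paths"]


@dataclass
class HubReport:
    nodes: list[str]
    mean_degree: list[float]
    sd_degree: list[float]
    degree_distribution: list[dict[int, int]]  # per node: degree -> tree count
    archive_size: int
    mode: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ranked(self) -> list[tuple[str, float]]:
        """Nodes sorted by mean degree, descending; label breaks ties."""
        return sorted(
            zip(self.nodes, self.mean_degree), key=lambda t: (-t[1], t[0])
        )


def average_degrees(archive: TreeArchive) -> HubReport:
    """Per-node mean (and sd) of tree degree across every archived tree.

    The means always sum to 2(N-1): each tree contributes exactly N-1 edges.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")
    trees = list(archive.trees.values())
    nodes = trees[0].graph.nodes
    n = len(nodes)
    k = len(trees)
    sums = [0] * n
    sq = [0] * n
    dist: list[dict[int, int]] = [{} for _ in range(n)]
    for tree in trees:
        for i, d in enumerate(tree.degrees()):
            sums[i] += d
            sq[i] += d * d
            dist[i][d] = dist[i].get(d, 0) + 1
    mean = [s / k for s in sums]
    sd = [math.sqrt(max(sq[i] / k - mean[i] ** 2, 0.0)) for i in range(n)]
    return HubReport(
        nodes=list(nodes),
        mean_degree=mean,
        sd_degree=sd,
        degree_distribution=dist,
        archive_size=k,
        mode=archive.mode,
    )


def identify_hubs(
    report: HubReport, rule: str = "above_mean", k: int | None = None
) -> list[str]:
    """Call hubs from a degree report.

    ``above_mean``: nodes with mean degree strictly above the tree-wide
    average 2(N-1)/N.  ``top_k``: the ``k`` highest mean degrees, ties broken
    by label.
    """
    n = report.n_nodes
    if rule == "above_mean":
        threshold = 2 * (n - 1) / n
        return [
            node
            for node, m in zip(report.nodes, report.mean_degree)
            if m > threshold
        ]
    if rule == "top_k":
        if k is None:
            raise ValueError("top_k rule requires k")
        if k > n:
            raise ValueError(f"k={k} exceeds node count {n}")
        return [node for node, _ in report.ranked()[:k]]
    raise ValueError(f"unknown hub rule {rule!r}")


def hub_connecting_paths(
    net: Network, hub_a: str, hub_b: str, max_length: int = 2
) -> list[list[str]]:
    """All simple paths between two hubs in the undirected projection with at
    most ``max_length`` intermediate nodes, shortest first.

    These are the candidate transition pathways: a path joining two hubs that
    regulate different cell states is a structural candidate for driving the
    transition between those states.
    """
    for h in (hub_a, hub_b):
        if h not in net.nodes:
            raise ValueError(f"unknown node {h!r}")
    g = undirected_projection(net).to_networkx()
    paths = nx.all_simple_paths(g, hub_a, hub_b, cutoff=max_length + 1)
    return sorted(paths, key=lambda p: (len(p), p))
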