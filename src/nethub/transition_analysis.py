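"""Trajectory analysis: LCS distance series and increase/decrease patterns.

The distance between the instantaneous network state and the target state is
the longest-common-subsequence (LCS) distance

    d_LCS(v1, v2) = A(v1, v1) + A(v2, v2) - 2 A(v1, v2)

where A is LCS length: the cost in insertions and deletions of transforming
one binary vector into the other.  Tracked over a transition run, the series
alternately approaches and retreats from the target; segmenting it into
maximal windows whose strict changes share one sign (plateaus absorbed)
yields *distance-decreasing* and *distance-increasing* patterns, and the
nodes updated at the strict changes of each pattern are the TFs driving the
state toward or away from the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolean_sim import NetworkState, Trajectory

__all__ = [
    "DistanceSeries",
    "Pattern",
    "lcs_length",
    "lcs_distance",
    "hamming_distance",
    "distance_series",
    "extract_patterns",
    "tf_pattern_frequencies",
    "tf_increase_counts",
    "tf_on_probability_at_decrease_initiation",
]

DECREASING = "decreasing"
INCREASING = "increasing"


def _as_binary(v) -> np.ndarray:
    if isinstance(v, NetworkState):
        return np.asarray(v.bits, dtype=np.int8)
    arr = np.asarray(v)
    if arr.ndim != 1 or np.any((arr != 0) & (arr != 1)):
        raise ValueError("inputs must be 1-D binary vectors")
    return arr.astype(np.int8)


def lcs_length(v1, v2) -> int:
    """Longest-common-subsequence length of two binary vectors.

    Classic O(len1*len2) dynamic program over a rolling row; the vectors may
    differ in length.  A(v, v) = len(v).
    """
    a, b = _as_binary(v1), _as_binary(v2)
    if a.size == 0 or b.size == 0:
        return 0
    prev = np.zeros(b.size + 1, dtype=np.int64)
    cur = np.zeros(b.size + 1, dtype=np.int64)
    for x in a:
        match = b == x
        cur[1:] = np.where(match, prev[:-1] + 1, 0)
        np.maximum.accumulate(np.maximum(cur[1:], prev[1:]), out=cur[1:])
        prev, cur = cur, prev
    return int(prev[-1])


def lcs_distance(v1, v2) -> int:
    """d_LCS = A(v1,v1) + A(v2,v2) - 2 A(v1,v2); insert+delete edit cost."""
    a, b = _as_binary(v1), _as_binary(v2)
    return int(a.size) + int(b.size) - 2 * lcs_length(a, b)


def hamming_distance(v1, v2) -> int:
    """Alternative metric for equal-length vectors (config flag only)."""
    a, b = _as_binary(v1), _as_binary(v2)
    if a.size != b.size:
        raise ValueError("Hamming distance requires equal lengths")
    return int(np.sum(a != b))


@dataclass
class DistanceSeries:
    """Distance to target after every iteration of one trajectory.

    ``distances[0]`` is the distance of the (clamped) initial state;
    ``distances[t]`` the distance after iteration t, so the series has
    ``iterations + 1`` entries aligned with the per-iteration update log.
    """

    distances: np.ndarray
    updated_nodes: list[str]
    trajectory: Trajectory
    target: NetworkState

    @property
    def n_steps(self) -> int:
        return len(self.updated_nodes)

    def step_deltas(self) -> np.ndarray:
        return np.diff(self.distances)


def distance_series(
    trajectory: Trajectory, target: NetworkState, metric: str = "lcs"
) -> DistanceSeries:
    """Evaluate the distance to ``target`` after every iteration by replay."""
    if len(target.nodes) != len(trajectory.initial.nodes):
        raise ValueError("target length does not match trajectory states")
    dist_fn = {"lcs": lcs_distance, "hamming": hamming_distance}.get(metric)
    if dist_fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    nodes = trajectory.initial.nodes
    out = np.empty(trajectory.iterations + 1, dtype=np.int64)
    out[0] = dist_fn(trajectory.initial.bits, target.bits)
    updated = []
    bits = trajectory.initial.bits.copy()
    for t, (i, b) in enumerate(zip(trajectory.updated_nodes, trajectory.new_bits)):
        old = bits[i]
        bits[i] = b
        if b == old:
            out[t + 1] = out[t]  # no-op update cannot move the distance
        else:
            out[t + 1] = dist_fn(bits, target.bits)
        updated.append(nodes[i])
    if trajectory.converged and out[-1] != 0:
        raise AssertionError("converged trajectory must end at distance 0")
    return DistanceSeries(out, updated, trajectory, target)


@dataclass
class Pattern:
    """A maximal window whose strict distance changes share one sign."""

    kind: str  # "decreasing" | "increasing"
    start: int  # first step index in the window (1-based over distances)
    end: int  # one past the last step index (half-open)
    nodes: list[str]  # nodes updated at strict-change steps, in order
    initiating_state: NetworkState  # state at the window start

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)


def extract_patterns(
    series: DistanceSeries, min_strict_changes: int = 1
) -> list[Pattern]:
    """Segment a distance series into increase/decrease patterns.

    Walks the per-step deltas: a strict change opens a window (or extends the
    current one if the sign matches), a plateau is absorbed into the open
    window, and an opposite-sign strict change closes the window and opens a
    new one.  Leading/trailing plateau stretches belong to no pattern, so
    every strict change is covered by exactly one pattern.  Windows with
    fewer than ``min_strict_changes`` strict changes are dropped (default 1
    keeps everything).
    """
    deltas = series.step_deltas()
    if deltas.size == 0:
        return []
    traj = series.trajectory
    nodes_per_step = series.updated_nodes

    # states at window starts, gathered in one replay pass
    patterns: list[Pattern] = []
    current_kind: str | None = None
    current_start = 0  # step index (1-based: step t moves distances[t-1]->[t])
    current_nodes: list[str] = []
    current_strict = 0
    current_init: NetworkState | None = None

    bits = traj.initial.bits.copy()
    node_list = traj.initial.nodes

    def snapshot() -> NetworkState:
        return NetworkState(list(node_list), bits.copy())

    last_step_of_window = 0
    for step in range(1, deltas.size + 1):
        d = deltas[step - 1]
        if d != 0:
            kind = DECREASING if d < 0 else INCREASING
            if current_kind is None:
                current_kind = kind
                current_start = step
                current_init = snapshot()
                current_nodes = []
                current_strict = 0
            elif kind != current_kind:
                # close previous window at its last step, open a new one
                end_step = last_step_of_window
                if current_strict >= min_strict_changes:
                    patterns.append(
                        Pattern(
                            kind=current_kind,
                            start=current_start,
                            end=end_step + 1,
                            nodes=current_nodes,
                            initiating_state=current_init,
                        )
                    )
                current_kind = kind
                current_start = step
                current_init = snapshot()
                current_nodes = []
                current_strict = 0
            current_nodes.append(nodes_per_step[step - 1])
            current_strict += 1
            last_step_of_window = step
        elif current_kind is not None:
            last_step_of_window = step  # plateau absorbed into the open window
        # advance replay state
        i = traj.updated_nodes[step - 1]
        bits[i] = traj.new_bits[step - 1]
    if current_kind is not None and current_strict >= min_strict_changes:
        patterns.append(
            Pattern(
                kind=current_kind,
                start=current_start,
                end=last_step_of_window + 1,
                nodes=current_nodes,
                initiating_state=current_init,
            )
        )
    return patterns


def tf_pattern_frequencies(
    patterns: list[Pattern], nodes: list[str]
) -> dict[str, dict[str, int]]:
    """Count, per node, the patterns it appears in (once per pattern).

    Returns ``{"decreasing": {node: count}, "increasing": {node: count}}``.
    Only strict-change steps attribute nodes to a pattern.
    """
    out = {
        DECREASING: {n: 0 for n in nodes},
        INCREASING: {n: 0 for n in nodes},
    }
    for pat in patterns:
        table = out[pat.kind]
        for n in pat.node_set:
            table[n] += 1
    return out


def tf_increase_counts(
    series_list: list[DistanceSeries], nodes: list[str]
) -> dict[str, int]:
    """Per node: number of iterations whose update strictly increased the
    distance, summed over the ensemble."""
    counts = {n: 0 for n in nodes}
    for series in series_list:
        deltas = series.step_deltas()
        for step_node, d in zip(series.updated_nodes, deltas):
            if d > 0:
                counts[step_node] += 1
    return counts


def tf_on_probability_at_decrease_initiation(
    patterns: list[Pattern], nodes: list[str]
) -> dict[str, float]:
    """Fraction of decreasing patterns whose initiating state has each node ON."""
    dec = [p for p in patterns if p.kind == DECREASING]
    if not dec:
        raise ValueError("no decreasing patterns to analyze")
    on = {n: 0 for n in nodes}
    for pat in dec:
        st = pat.initiating_state
        for n in nodes:
            on[n] += int(st.bits[st.index[n]])
    return {n: on[n] / len(dec) for n in nodes}
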