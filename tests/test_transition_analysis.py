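from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nethub.boolean_sim import ClampSpec, NetworkState, Trajectory, run_transition
from nethub.transition_analysis import (
    DECREASING,
    INCREASING,
    distance_series,
    extract_patterns,
    hamming_distance,
    lcs_distance,
    lcs_length,
    tf_increase_counts,
    tf_on_probability_at_decrease_initiation,
    tf_pattern_frequencies,
)


def lcs_oracle(a, b):
    """Independent recursive-memoized LCS length (top-down, not the DP row)."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(a), len(b))


def make_trajectory(nodes, initial_bits, steps, converged=False):
    """Hand-built trajectory from (node_label, new_bit) steps."""
    init = NetworkState(list(nodes), np.array(initial_bits))
    idx = {n: k for k, n in enumerate(nodes)}
    updated = [idx[n] for n, _ in steps]
    bits = [b for _, b in steps]
    final = init.copy()
    for i, b in zip(updated, bits):
        final.bits[i] = b
    return Trajectory(
        initial=init, updated_nodes=updated, new_bits=bits,
        converged=converged, iterations=len(steps), seed=0, final=final,
    )


class TestLCS:
    def test_self_match_is_length(self):
        v = (1, 0, 1, 1, 0)
        assert lcs_length(v, v) == 5

    def test_hand_computed_pair(self):
        assert lcs_length((1, 0, 1, 1, 0), (0, 1, 1, 0, 1)) == 4

    def test_disjoint_alphabets(self):
        assert lcs_length((1, 1, 1), (0, 0, 0)) == 0

    def test_different_lengths_allowed(self):
        assert lcs_length((1, 0, 1), (1, 0, 1, 0, 1)) == 3

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lcs_length((1, 2, 0), (1, 0, 0))

    def test_distance_identity(self):
        assert lcs_distance((1, 0, 1), (1, 0, 1)) == 0

    def test_distance_hand_computed(self):
        assert lcs_distance((1, 0, 1, 1, 0), (0, 1, 1, 0, 1)) == 2

    @pytest.mark.parametrize("m", [1, 4, 9])
    def test_disjoint_vectors_attain_maximum_2m(self, m):
        # all-ones vs all-zeros share no common subsequence, so A = 0
        assert lcs_distance((1,) * m, (0,) * m) == 2 * m

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 1), min_size=0, max_size=18),
        b=st.lists(st.integers(0, 1), min_size=0, max_size=18),
    )
    def test_metric_properties_against_oracle(self, a, b):
        d = lcs_distance(a, b)
        assert d == len(a) + len(b) - 2 * lcs_oracle(a, b)
        assert d >= 0
        assert lcs_distance(b, a) == d
        if len(a) == len(b):
            assert d % 2 == 0  # 2(m - LCS) for equal lengths
            assert (d == 0) == (list(a) == list(b))

    def test_hamming_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal"):
            hamming_distance((1, 0), (1, 0, 1))


class TestDistanceSeries:
    def test_converged_series_ends_at_zero(self, bistable):
        _, rules, states = bistable
        traj = run_transition(
            rules, states["NONNE_like"], states["NE_like"],
            ClampSpec.of(on=("H1", "BR")), 20000, seed=4,
        )
        assert traj.converged
        series = distance_series(traj, states["NE_like"])
        assert series.distances[-1] == 0
        assert len(series.distances) == traj.iterations + 1

    def test_single_flip_toward_target_drops_by_two(self):
        nodes = ["A", "B", "C"]
        traj = make_trajectory(nodes, (0, 1, 1), [("A", 1)])
        target = NetworkState(nodes, np.array([1, 1, 1]))
        series = distance_series(traj, target)
        before = lcs_distance((0, 1, 1), (1, 1, 1))
        assert list(series.distances) == [before, before - 2]

    def test_noop_update_keeps_distance(self):
        nodes = ["A", "B"]
        traj = make_trajectory(nodes, (0, 1), [("A", 0), ("A", 0)])
        target = NetworkState(nodes, np.array([1, 1]))
        series = distance_series(traj, target)
        assert series.distances[0] == series.distances[1] == series.distances[2]

    def test_accounting_conservation(self, bistable):
        # strict increases + strict decreases + plateaus == iterations
        _, rules, states = bistable
        traj = run_transition(
            rules, states["NONNE_like"], states["NE_like"],
            ClampSpec.of(on=("H1",)), 20000, seed=11,
        )
        series = distance_series(traj, states["NE_like"])
        deltas = series.step_deltas()
        inc, dec, flat = (deltas > 0).sum(), (deltas < 0).sum(), (deltas == 0).sum()
        assert inc + dec + flat == traj.iterations


class TestExtractPatterns:
    def test_strictly_decreasing_series(self):
        nodes = ["A", "B", "C", "D"]
        traj = make_trajectory(
            nodes, (0, 0, 0, 1), [("A", 1), ("B", 1), ("C", 1)], converged=True
        )
        target = NetworkState(nodes, np.array([1, 1, 1, 1]))
        patterns = extract_patterns(distance_series(traj, target))
        assert len(patterns) == 1
        assert patterns[0].kind == DECREASING
        assert patterns[0].nodes == ["A", "B", "C"]

    def test_spec_shaped_series_five_five_four_four_six(self):
        # distances 5,5,4,4,6: a decreasing window through the plateau, then
        # one increasing step
        nodes = [f"N{i}" for i in range(6)]
        target = NetworkState(nodes, np.array([1] * 6))
        from nethub.transition_analysis import DistanceSeries

        base = make_trajectory(
            nodes, (0, 0, 0, 0, 0, 1),
            [("N0", 0), ("N1", 1), ("N2", 0), ("N3", 1)],
        )
        series = DistanceSeries(
            np.array([5, 5, 4, 4, 6]), ["N0", "N1", "N2", "N3"], base, target
        )
        patterns = extract_patterns(series)
        assert [p.kind for p in patterns] == [DECREASING, INCREASING]
        dec, inc = patterns
        assert dec.start == 2 and dec.end == 4  # the drop plus its plateau
        assert dec.nodes == ["N1"]
        assert inc.start == 4 and inc.nodes == ["N3"]

    def test_constant_series_has_no_patterns(self):
        nodes = ["A", "B"]
        traj = make_trajectory(nodes, (0, 1), [("A", 0), ("A", 0)])
        target = NetworkState(nodes, np.array([0, 1]))
        assert extract_patterns(distance_series(traj, target)) == []

    def test_every_strict_change_in_exactly_one_pattern(self, bistable):
        _, rules, states = bistable
        traj = run_transition(
            rules, states["NONNE_like"], states["NE_like"],
            ClampSpec.of(on=("H1", "BR")), 20000, seed=21,
        )
        series = distance_series(traj, states["NE_like"])
        patterns = extract_patterns(series)
        deltas = series.step_deltas()
        strict_steps = {i + 1 for i, d in enumerate(deltas) if d != 0}
        covered = []
        for p in patterns:
            covered.extend(
                s for s in range(p.start, p.end) if deltas[s - 1] != 0
            )
        assert sorted(covered) == sorted(strict_steps)  # no gaps, no overlaps
        # windows are disjoint and ordered
        for a, b in zip(patterns, patterns[1:]):
            assert a.end <= b.start

    def test_converged_run_ends_with_decreasing_pattern(self, bistable):
        _, rules, states = bistable
        traj = run_transition(
            rules, states["NONNE_like"], states["NE_like"],
            ClampSpec.of(on=("H1", "BR")), 20000, seed=33,
        )
        assert traj.converged
        series = distance_series(traj, states["NE_like"])
        patterns = extract_patterns(series)
        assert patterns[-1].kind == DECREASING
        assert series.distances[patterns[-1].end - 1] == 0

    def test_min_strict_changes_filter(self):
        from nethub.transition_analysis import DistanceSeries

        nodes = ["A", "B"]
        base = make_trajectory(nodes, (0, 1), [("A", 1), ("A", 0), ("A", 1)])
        target = NetworkState(nodes, np.array([1, 1]))
        series = DistanceSeries(np.array([3, 2, 3, 2]), ["A", "A", "A"], base, target)
        assert len(extract_patterns(series)) == 3
        assert extract_patterns(series, min_strict_changes=2) == []


class TestPatternStatistics:
    def _patterns(self):
        from nethub.transition_analysis import Pattern

        s_on = NetworkState(["A", "B", "C"], np.array([1, 0, 1]))
        s_off = NetworkState(["A", "B", "C"], np.array([0, 0, 1]))
        return [
            Pattern(DECREASING, 1, 4, ["A", "B", "A"], s_on),
            Pattern(DECREASING, 6, 8, ["C"], s_off),
            Pattern(INCREASING, 9, 10, ["C"], s_on),
        ]

    def test_empty_pattern_list(self):
        freq = tf_pattern_frequencies([], ["A", "B"])
        assert freq["decreasing"] == {"A": 0, "B": 0}
        assert freq["increasing"] == {"A": 0, "B": 0}

    def test_node_counted_once_per_pattern(self):
        freq = tf_pattern_frequencies(self._patterns(), ["A", "B", "C"])
        assert freq["decreasing"] == {"A": 1, "B": 1, "C": 1}
        assert freq["increasing"] == {"A": 0, "B": 0, "C": 1}

    def test_on_probability_at_decrease_initiation(self):
        probs = tf_on_probability_at_decrease_initiation(
            self._patterns(), ["A", "B", "C"]
        )
        assert probs == {"A": 0.5, "B": 0.0, "C": 1.0}

    def test_on_probability_requires_decreasing_patterns(self):
        with pytest.raises(ValueError, match="no decreasing"):
            tf_on_probability_at_decrease_initiation([], ["A"])

    def test_increase_counts_hand_built(self):
        from nethub.transition_analysis import DistanceSeries

        nodes = ["A", "B", "C"]
        base = make_trajectory(
            nodes, (0, 0, 0), [("A", 1), ("B", 1), ("C", 1), ("B", 0)]
        )
        target = NetworkState(nodes, np.array([1, 1, 0]))
        series = DistanceSeries(
            np.array([4, 2, 0, 2, 0]), ["A", "B", "C", "B"], base, target
        )
        counts = tf_increase_counts([series], nodes)
        assert counts == {"A": 0, "B": 0, "C": 1}
        assert sum(counts.values()) == int((series.step_deltas() > 0).sum())

    def test_clamped_nodes_never_in_increase_counts(self, bistable):
        _, rules, states = bistable
        series_list = []
        for seed in range(5):
            traj = run_transition(
                rules, states["NONNE_like"], states["NE_like"],
                ClampSpec.of(on=("H1", "BR")), 20000, seed=seed,
            )
            series_list.append(distance_series(traj, states["NE_like"]))
        counts = tf_increase_counts(series_list, rules.nodes)
        assert counts["H1"] == 0 and counts["BR"] == 0
        # clamped nodes likewise never appear in increasing patterns
        patterns = [p for s in series_list for p in extract_patterns(s)]
        freq = tf_pattern_frequencies(patterns, rules.nodes)
        assert freq["increasing"]["H1"] == 0 and freq["increasing"]["BR"] == 0
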