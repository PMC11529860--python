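import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecrecon.io import CycleRecord
from ecrecon.metrics import (
    LENGTH_ERROR_FLOOR,
    breakpoint_graph_accuracy,
    cycle_interval_overlap,
    cyclic_lcs,
    evaluate_pair,
    length_error,
)
from ecrecon.model import Breakend, BreakpointGraph, DiscordantEdge, SequenceEdge
from ecrecon.simulate import SyntheticReference, simulate_structure


def graph_with_junctions(pairs):
    g = BreakpointGraph(amplicon_id=1)
    g.add(SequenceEdge("chr1", 1, 1_000_000, cn=1.0))
    for a, b in pairs:
        g.add(DiscordantEdge(Breakend(*a), Breakend(*b), cn=1.0))
    return g


def cycle(*segments, cn=10.0, index=1):
    return CycleRecord(index=index, copy_number=cn, is_cycle=True, segments=list(segments))


JUNCTIONS = [
    (("chr1", 10_000, "+"), ("chr1", 50_001, "-")),
    (("chr1", 80_000, "+"), ("chr1", 80_000, "+")),
    (("chr1", 120_000, "-"), ("chr1", 200_000, "-")),
    (("chr1", 300_000, "+"), ("chr1", 400_000, "-")),
]


class TestBreakpointGraphAccuracy:
    def test_identical_graphs_score_one(self):
        t = graph_with_junctions(JUNCTIONS)
        r = graph_with_junctions(JUNCTIONS)
        assert breakpoint_graph_accuracy(t, r) == 1.0

    def test_shift_beyond_tolerance_fails_that_edge(self):
        t = graph_with_junctions(JUNCTIONS[:1])
        shifted = [(("chr1", 10_150, "+"), ("chr1", 50_001, "-"))]
        r = graph_with_junctions(shifted)
        assert breakpoint_graph_accuracy(t, r, tolerance=100) == 0.0
        assert breakpoint_graph_accuracy(t, r, tolerance=200) == 1.0

    def test_partial_recovery_fraction(self):
        t = graph_with_junctions(JUNCTIONS)  # 4 truth edges
        r = graph_with_junctions(JUNCTIONS[:3])  # 3 recovered
        assert breakpoint_graph_accuracy(t, r) == 0.75

    def test_one_to_one_matching_not_many_to_one(self):
        # two near-identical truth edges vs a single reconstructed edge:
        # only one may match
        t = graph_with_junctions(
            [
                (("chr1", 10_000, "+"), ("chr1", 50_001, "-")),
                (("chr1", 10_050, "+"), ("chr1", 50_050, "-")),
            ]
        )
        r = graph_with_junctions([(("chr1", 10_020, "+"), ("chr1", 50_020, "-"))])
        assert breakpoint_graph_accuracy(t, r) == 0.5

    def test_orientation_must_match(self):
        t = graph_with_junctions(JUNCTIONS[:1])
        r = graph_with_junctions([(("chr1", 10_000, "-"), ("chr1", 50_001, "-"))])
        assert breakpoint_graph_accuracy(t, r) == 0.0

    def test_monotone_under_truth_edge_deletion(self):
        t = graph_with_junctions(JUNCTIONS)
        scores = [
            breakpoint_graph_accuracy(t, graph_with_junctions(JUNCTIONS[:k]))
            for k in range(len(JUNCTIONS), -1, -1)
        ]
        assert scores == sorted(scores, reverse=True)


class TestCycleIntervalOverlap:
    def test_order_independence(self):
        a = cycle(("chr1", 1, 100, "+"), ("chr1", 201, 300, "+"))
        b = cycle(("chr1", 201, 300, "+"), ("chr1", 1, 100, "+"))
        assert cycle_interval_overlap(a, b) == 1.0

    def test_disjoint_intervals(self):
        a = cycle(("chr1", 1, 100, "+"))
        b = cycle(("chr2", 1, 100, "+"))
        assert cycle_interval_overlap(a, b) == 0.0

    def test_partial_overlap_jaccard(self):
        a = cycle(("chr1", 1, 100, "+"))
        b = cycle(("chr1", 51, 150, "+"))
        assert cycle_interval_overlap(a, b) == pytest.approx(50 / 150)

    def test_multiplicity_ignored(self):
        a = cycle(("chr1", 1, 100, "+"), ("chr1", 1, 100, "+"))
        b = cycle(("chr1", 1, 100, "+"))
        assert cycle_interval_overlap(a, b) == 1.0


SEGS = [("chr1", 1, 100, "+"), ("chr1", 101, 200, "+"), ("chr1", 201, 300, "+"), ("chr1", 301, 400, "+")]


class TestCyclicLCS:
    def test_identical_cycles(self):
        assert cyclic_lcs(cycle(*SEGS), cycle(*SEGS)) == 1.0

    def test_rotation_invariance(self):
        rotated = cycle(*SEGS[2:], *SEGS[:2])
        assert cyclic_lcs(cycle(*SEGS), rotated) == 1.0

    def test_orientation_flip_invariance(self):
        flipped = cycle(*[(c, s, e, "-") for c, s, e, _ in reversed(SEGS)])
        assert cyclic_lcs(cycle(*SEGS), flipped) == 1.0

    def test_swapped_middle_segments(self):
        # truth A,B,C,D vs A,C,B,D (equal lengths): best LCS keeps 3 of 4
        a, b, c, d = SEGS
        assert cyclic_lcs(cycle(a, b, c, d), cycle(a, c, b, d)) == pytest.approx(0.75)

    def test_unshared_segments_eliminated(self):
        extra = ("chr2", 1, 100, "+")
        assert cyclic_lcs(cycle(*SEGS), cycle(*SEGS, extra)) == 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(rot_t=st.integers(0, 3), rot_r=st.integers(0, 3), flip=st.booleans())
    def test_rotation_and_flip_invariance_property(self, rot_t, rot_r, flip):
        t_segs = SEGS[rot_t:] + SEGS[:rot_t]
        r_segs = SEGS[rot_r:] + SEGS[:rot_r]
        if flip:
            r_segs = [(c, s, e, "-") for c, s, e, _ in reversed(r_segs)]
        assert cyclic_lcs(cycle(*t_segs), cycle(*r_segs)) == 1.0


class TestLengthError:
    def test_exact_match_reports_floor_and_flag(self):
        a = cycle(("chr1", 1, 1000, "+"))
        err = length_error(a, cycle(("chr1", 2001, 3000, "+")))
        assert err.exact_match
        assert err.value == pytest.approx(math.log2(LENGTH_ERROR_FLOOR))

    def test_double_length_gives_log2_one_ratio(self):
        a = cycle(("chr1", 1, 1000, "+"))
        b = cycle(("chr1", 1, 2000, "+"))
        assert length_error(a, b).value == pytest.approx(math.log2(1 + LENGTH_ERROR_FLOOR))

    def test_half_extra_gives_minus_one(self):
        a = cycle(("chr1", 1, 1000, "+"))
        b = cycle(("chr1", 1, 1500, "+"))
        assert length_error(a, b).value == pytest.approx(
            math.log2(0.5 + LENGTH_ERROR_FLOOR), abs=1e-6
        )


class TestSelfComparison:
    @pytest.mark.parametrize("mechanism", ["episomal", "chromothripsis", "2-foldback"])
    def test_simulated_amplicon_scores_perfect_against_itself(self, mechanism):
        ref = SyntheticReference({"chr1": 1_500_000})
        rng = np.random.default_rng(5)
        amp = simulate_structure(ref, mechanism, 4, rng)
        report = evaluate_pair(
            amp.true_graph,
            amp.true_cycle_record(),
            amp.true_graph,
            [amp.true_cycle_record()],
        )
        assert report.breakpoint_graph_accuracy == 1.0
        assert report.cycle_interval_overlap == 1.0
        assert report.cyclic_lcs == 1.0
        assert report.exact_length
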