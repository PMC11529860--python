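import numpy as np
import pytest

from _oracle import best_full_objective, decomposition_objective, random_small_graph
from conftest import abbc_constraint, make_abc_graph
from ecrecon.cycles import (
    INFEASIBLE,
    ExtractionConfig,
    SubwalkConstraint,
    Walk,
    estimate_multiplicity_caps,
    extract_cycles,
    heaviest_cycles,
    satisfies_subwalk,
    solve_miqcp_full,
    solve_miqcp_greedy,
)
from ecrecon.model import (
    Breakend,
    BreakpointGraph,
    DiscordantEdge,
    SequenceEdge,
)


def simple_cycle_graph(cn=12.0, n_cycles=1, length=1):
    """n disjoint single-segment circles, each of copy number cn."""
    g = BreakpointGraph(amplicon_id=1)
    for i in range(n_cycles):
        start = 1 + i * (length + 10)
        end = start + length - 1
        g.add(SequenceEdge("chr1", start, end, cn=cn))
        g.add(
            DiscordantEdge(
                Breakend("chr1", end, "+"), Breakend("chr1", start, "-"), cn=cn,
                max_multiplicity=1,
            )
        )
    g.sort()
    return g


class TestWorkedExamples:
    def test_single_cycle_duplicating_b(self, abc_single_cycle):
        graph, keys = abc_single_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        assert decomp is not INFEASIBLE
        assert len(decomp.walks) == 1
        (walk,) = decomp.walks
        assert walk.is_cycle
        assert walk.copy_number == pytest.approx(50.0)
        assert walk.edge_multiplicity[keys["B"]] == 2
        assert decomp.cn_fraction_explained == pytest.approx(1.0)
        assert decomp.subwalks_satisfied == 1

    def test_two_cycle_optimum(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        assert decomp is not INFEASIBLE
        assert sorted(round(w.copy_number, 6) for w in decomp.walks) == [10.0, 80.0]
        small = min(decomp.walks, key=lambda w: w.copy_number)
        assert small.edge_multiplicity[keys["B"]] == 2
        assert small.edge_multiplicity.get(keys["C"], 0) == 1
        top, frac = heaviest_cycles(decomp, 1)
        assert frac == pytest.approx(0.80)
        assert top[0].copy_number == pytest.approx(80.0)

    def test_greedy_order_on_two_cycle_graph(self, abc_two_cycle):
        # the Eq.7 maximizer is the copy-number-80 cycle (largest
        # length-weighted CN), then the copy-number-10 cycle
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_greedy(graph, [abbc_constraint(keys)])
        assert [round(w.copy_number, 6) for w in decomp.walks] == [80.0, 10.0]


class TestModesAgree:
    def test_full_and_greedy_identical_on_single_cycle(self):
        g = simple_cycle_graph(cn=9.0)
        full = solve_miqcp_full(g, [], k=10)
        greedy = solve_miqcp_greedy(g, [])
        for d in (full, greedy):
            assert len(d.walks) == 1
            assert d.walks[0].copy_number == pytest.approx(9.0)
            assert d.walks[0].is_cycle
            assert d.cn_fraction_explained == pytest.approx(1.0)
        assert full.walks[0].edge_multiplicity == greedy.walks[0].edge_multiplicity

    def test_deterministic_rerun(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        d1 = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        d2 = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        assert [(w.copy_number, w.edge_multiplicity) for w in d1.walks] == [
            (w.copy_number, w.edge_multiplicity) for w in d2.walks
        ]


class TestDriver:
    def test_full_mode_on_small_graph(self, abc_single_cycle):
        graph, keys = abc_single_cycle
        decomp = extract_cycles(graph, [abbc_constraint(keys)])
        assert decomp.mode == "full"
        assert decomp.k_used == 10

    def test_k_doubling_on_many_disjoint_cycles(self):
        # 12 disjoint cycles: k=10 cannot reach alpha=0.9, so the driver
        # must double k and succeed at k=20
        g = simple_cycle_graph(cn=5.0, n_cycles=12)
        assert solve_miqcp_full(g, [], k=10) is INFEASIBLE
        decomp = extract_cycles(g, [], ExtractionConfig(variable_cap=100_000))
        assert decomp.mode == "full"
        assert decomp.k_used == 20
        # the optimum stops at 11 walks: the 12th costs a full walk term
        # but gains only 1/12 of the mass term
        assert len(decomp.walks) == 11
        assert decomp.cn_fraction_explained == pytest.approx(11 / 12)

    def test_greedy_mode_for_large_graphs(self):
        g = simple_cycle_graph(cn=5.0, n_cycles=3)
        cfg = ExtractionConfig(full_mode_edge_cap=2)  # force the size branch
        decomp = extract_cycles(g, [], cfg)
        assert decomp.mode == "greedy"

    def test_epsilon_stopping_rule_skips_tiny_side_cycle(self):
        g = simple_cycle_graph(cn=100.0)
        g.add(SequenceEdge("chr1", 50, 50, cn=0.3))
        g.add(
            DiscordantEdge(
                Breakend("chr1", 50, "+"), Breakend("chr1", 50, "-"), cn=0.3,
                max_multiplicity=1,
            )
        )
        g.sort()
        decomp = solve_miqcp_greedy(g, [])
        assert len(decomp.walks) == 1
        assert decomp.walks[0].copy_number == pytest.approx(100.0)


class TestSubwalkSatisfaction:
    def test_cycle_containing_chain_satisfies(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        small = min(decomp.walks, key=lambda w: w.copy_number)
        big = max(decomp.walks, key=lambda w: w.copy_number)
        constraint = abbc_constraint(keys)
        assert satisfies_subwalk(small, constraint)
        assert not satisfies_subwalk(big, constraint)  # misses C and second B

    def test_empty_walk_never_satisfies(self, abc_two_cycle):
        _, keys = abc_two_cycle
        empty = Walk([], True, 0.0, {}, graph_id=1)
        assert not satisfies_subwalk(empty, abbc_constraint(keys))

    def test_cross_graph_comparison_rejected(self, abc_two_cycle):
        _, keys = abc_two_cycle
        walk = Walk([], True, 1.0, {keys["A"]: 1}, graph_id=2)
        with pytest.raises(ValueError):
            satisfies_subwalk(walk, abbc_constraint(keys, graph_id=1))


class TestHeaviestCycles:
    def test_exhaustive_k_returns_total_fraction(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        _, frac = heaviest_cycles(decomp, 10)
        assert frac == pytest.approx(decomp.cn_fraction_explained)

    def test_equal_weight_tie_broken_by_coordinate(self):
        g = simple_cycle_graph(cn=5.0, n_cycles=2)
        decomp = solve_miqcp_full(g, [], k=10)
        top, _ = heaviest_cycles(decomp, 2)
        assert top[0].first_coordinate() < top[1].first_coordinate()

    def test_k_below_one_rejected(self, abc_single_cycle):
        graph, keys = abc_single_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        with pytest.raises(ValueError):
            heaviest_cycles(decomp, 0)


class TestStructuralInvariants:
    def test_no_edge_over_explanation_and_r_caps(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        decomp.validate(graph)  # raises on over-explanation
        caps = {e.key(): e.max_multiplicity for e in graph.discordant_edges}
        for walk in decomp.walks:
            for key, mult in walk.edge_multiplicity.items():
                if key in caps:
                    assert mult <= caps[key]

    def test_walks_are_closed_alternating_sequences(self, abc_two_cycle):
        graph, keys = abc_two_cycle
        decomp = solve_miqcp_full(graph, [abbc_constraint(keys)], k=10)
        for walk in decomp.walks:
            assert walk.is_cycle
            assert walk.node_sequence[0] == walk.node_sequence[-1]
            assert walk.node_sequence[0].is_source is False


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_milp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        graph, constraints = random_small_graph(rng)
        oracle = best_full_objective(graph, constraints, max_walks=3)
        decomp = solve_miqcp_full(graph, constraints, k=3)
        if oracle is None:
            assert decomp is INFEASIBLE
        else:
            assert decomp is not INFEASIBLE
            assert decomposition_objective(decomp, graph) == pytest.approx(
                oracle, abs=1e-5
            )
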