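import numpy as np
import pytest

from ecrecon.intervals import (
    AmplifiedInterval,
    BreakpointCluster,
    CNVSegment,
    IntervalConnection,
    SearchConfig,
    bfs_interval_search,
    build_graph_structure,
    canonical_pair,
    cluster_breakpoints,
    extract_chimeric_breakpoints,
    merge_intervals,
    select_seeds,
)
from ecrecon.model import Breakend


def seg(chrom, start, end, cn, cov=13.0):
    return CNVSegment(chrom, start, end, cn, cov)


class TestSelectSeeds:
    def test_single_qualifying_run(self):
        segments = [seg("chr1", 1, 100_000, 2.0), seg("chr1", 100_001, 400_000, 20.0)]
        cfg = SearchConfig(seed_cn_min=5.0, seed_size_min=100_000)
        seeds = select_seeds(segments, cfg)
        assert [(s.chrom, s.start, s.end) for s in seeds] == [("chr1", 100_001, 400_000)]

    def test_short_run_filtered_by_aggregate_size(self):
        segments = [seg("chr1", 1, 40_000, 30.0)]
        assert select_seeds(segments, SearchConfig(seed_size_min=50_000)) == []

    def test_adjacent_runs_merge_and_gaps_split(self):
        # five-segment table: two adjacent qualifying segments merge into one
        # seed; a far-away qualifying run seeds separately
        segments = [
            seg("chr1", 1, 50_000, 2.0),
            seg("chr1", 50_001, 120_000, 8.0),
            seg("chr1", 120_001, 200_000, 12.0),
            seg("chr1", 200_001, 800_000, 2.0),
            seg("chr1", 800_001, 900_000, 9.0),
        ]
        seeds = select_seeds(segments, SearchConfig())
        assert [(s.start, s.end) for s in seeds] == [(50_001, 200_000), (800_001, 900_000)]

    def test_small_unamplified_gaps_do_not_break_a_run(self):
        # interleaved CNV profile of a shattered amplicon
        segments = [
            seg("chr1", 100_001, 140_000, 10.0),
            seg("chr1", 140_001, 160_000, 2.0),
            seg("chr1", 160_001, 200_000, 10.0),
        ]
        seeds = select_seeds(segments, SearchConfig(seed_gap_max=50_000))
        assert [(s.start, s.end) for s in seeds] == [(100_001, 200_000)]

    def test_empty_input(self):
        assert select_seeds([], SearchConfig()) == []


class TestClusterBreakpoints:
    def pair(self, pa, pb, oa="+", ob="-"):
        return canonical_pair(Breakend("chr1", pa, oa), Breakend("chr1", pb, ob))

    def test_identical_pairs_form_one_cluster(self):
        raw = [self.pair(10_000, 50_001)] * 12
        clusters = cluster_breakpoints(raw, window=100, min_support=6)
        assert len(clusters) == 1
        assert clusters[0].support == 12
        assert not clusters[0].low_confidence

    def test_greedy_window_partition(self):
        # positions {10000, 10030, 10900}: same partition as brute-force
        # all-pairs distance clustering at window 100
        raw = [self.pair(p, 50_001) for p in (10_000, 10_030, 10_900)]
        clusters = cluster_breakpoints(raw, window=100, min_support=1)
        supports = sorted(c.support for c in clusters)
        assert supports == [1, 2]
        reps = sorted(c.breakend_a.position for c in clusters)
        assert reps == [10_015, 10_900]

    def test_low_support_clusters_flagged_not_dropped(self):
        raw = [self.pair(10_000, 50_001)] * 3
        clusters = cluster_breakpoints(raw, window=100, min_support=6)
        assert len(clusters) == 1 and clusters[0].low_confidence

    def test_representative_is_support_weighted_median(self):
        raw = [self.pair(p, 50_001) for p in (10_000, 10_000, 10_000, 10_060)]
        (cluster,) = cluster_breakpoints(raw, window=100, min_support=1)
        assert cluster.breakend_a.position == 10_000

    def test_window_validated(self):
        with pytest.raises(ValueError):
            cluster_breakpoints([], window=0, min_support=1)


class TestBFSAndMerge:
    def test_isolated_seed_yields_single_interval(self, episomal_dataset):
        from ecrecon.io import AlignmentSource, read_cnv_calls

        segments = read_cnv_calls(episomal_dataset.cnv_path)
        cfg = SearchConfig(delta=20_000)
        seeds = select_seeds(segments, cfg)
        with AlignmentSource(episomal_dataset.bam_path) as aln:
            intervals, connections = bfs_interval_search(seeds, aln, segments, cfg, 13.0)
        assert len(intervals) == 1
        # junctions internal to the seed give at most a self-connection
        assert all(c.interval_a is c.interval_b for c in connections)
        assert intervals[0].visited

    def test_new_interval_extension_formula(self):
        # far locus l inside an amplified CNV segment (chr2, 1-300k) with
        # delta=10k, Delta=200k: new interval clamps to chr2:1-310,000
        from unittest.mock import MagicMock

        from ecrecon.io import ReadFragment

        l = 150_000
        chain = [
            ReadFragment("r", "chr1", 95_000, 100_000, "+", 0, 5_001),
            ReadFragment("r", "chr2", l + 1, l + 5_000, "+", 5_001, 10_001),
        ]
        aln = MagicMock()
        aln.references = {"chr1": 1_000_000, "chr2": 1_000_000}

        def chains(chrom, start, end):
            return [chain] if chrom == "chr1" else []

        aln.chimeric_chains.side_effect = chains
        segments = [seg("chr1", 50_001, 100_000, 10.0), seg("chr2", 1, 300_000, 10.0)]
        cfg = SearchConfig(delta=10_000, big_delta=200_000, min_support_floor=1)
        seeds = select_seeds(segments, SearchConfig(seed_cn_min=5, seed_size_min=50_000))
        intervals, connections = bfs_interval_search(seeds, aln, segments, cfg, theta=2.0)
        new = [iv for iv in intervals if iv.chrom == "chr2"]
        assert [(iv.start, iv.end) for iv in new] == [(1, 310_000)]
        assert len(connections) == 1 and len(connections[0].labels) == 1

    def test_merge_overlapping_intervals(self):
        ivs = [AmplifiedInterval("chr1", 1, 100_000), AmplifiedInterval("chr1", 90_000, 200_000)]
        merged, _ = merge_intervals(ivs, [], delta=20_000)
        assert [(v.start, v.end) for v in merged] == [(1, 200_000)]

    def test_merge_connected_intervals_within_2delta(self):
        ivs = [AmplifiedInterval("chr1", 1, 100_000), AmplifiedInterval("chr1", 130_001, 200_000)]
        cluster = BreakpointCluster(
            Breakend("chr1", 99_000, "+"), Breakend("chr1", 131_000, "-"), support=10
        )
        conns = [IntervalConnection(ivs[0], ivs[1], [cluster])]
        merged, _ = merge_intervals(ivs, conns, delta=20_000)  # gap 30k <= 2*delta
        assert [(v.start, v.end) for v in merged] == [(1, 200_000)]

    def test_unconnected_gap_not_merged_and_cross_chrom_never_merged(self):
        ivs = [
            AmplifiedInterval("chr1", 1, 100_000),
            AmplifiedInterval("chr1", 130_001, 200_000),
            AmplifiedInterval("chr2", 1, 100_000),
        ]
        merged, _ = merge_intervals(ivs, [], delta=20_000)
        assert len(merged) == 3

    def test_merging_unifies_amplicons(self):
        ivs = [AmplifiedInterval("chr1", 1, 100_000), AmplifiedInterval("chr1", 50_000, 200_000)]
        merged, _ = merge_intervals(ivs, [], delta=20_000)
        assert len({v.amplicon_id for v in merged}) == 1


class TestBuildGraphStructure:
    def interval(self, start=1, end=100_000):
        return AmplifiedInterval("chr1", start, end, visited=True)

    def test_single_internal_breakend_splits_interval(self):
        p = 40_000
        clusters = [
            BreakpointCluster(Breakend("chr1", p, "+"), Breakend("chr1", 80_000, "-"), 10)
        ]
        g = build_graph_structure([self.interval()], clusters)
        starts = [(e.start, e.end) for e in g.sequence_edges]
        assert (1, p) in starts and (p + 1, 80_000 - 1) in starts
        assert len(g.concordant_edges) == 2
        assert len(g.discordant_edges) == 1

    def test_degenerate_interval_one_sequence_edge(self):
        g = build_graph_structure([self.interval()], [])
        assert len(g.sequence_edges) == 1
        assert len(g.concordant_edges) == 0
        assert {e.source for e in g.source_edges} == {"s", "t"}

    def test_worked_example_topology_edge_counts(self):
        # one interval split into A|B|C by junctions closing A->B->B->C
        iv = self.interval(1, 30_000)
        clusters = [
            BreakpointCluster(Breakend("chr1", 20_000, "+"), Breakend("chr1", 10_001, "-"), 10),
            BreakpointCluster(Breakend("chr1", 30_000, "+"), Breakend("chr1", 1, "-"), 10),
        ]
        g = build_graph_structure([iv], clusters)
        assert len(g.sequence_edges) == 3
        assert len(g.concordant_edges) == 2
        assert len(g.discordant_edges) == 2

    def test_sequence_edges_tile_each_interval_exactly(self):
        iv = self.interval(5_000, 90_000)
        clusters = [
            BreakpointCluster(Breakend("chr1", 50_000, "+"), Breakend("chr1", 20_000, "-"), 9)
        ]
        g = build_graph_structure([iv], clusters)
        edges = sorted((e.start, e.end) for e in g.sequence_edges)
        assert edges[0][0] == iv.start and edges[-1][1] == iv.end
        for (s1, e1), (s2, e2) in zip(edges, edges[1:]):
            assert s2 == e1 + 1

    def test_breakend_outside_intervals_is_an_error(self):
        clusters = [
            BreakpointCluster(Breakend("chr1", 40_000, "+"), Breakend("chr9", 1_000, "-"), 10)
        ]
        with pytest.raises(ValueError, match="outside"):
            build_graph_structure([self.interval()], clusters)

    def test_nearby_cuts_snap_to_one_boundary(self):
        # the two breakends of an inversion straddle the same boundary;
        # no sliver sequence edge may remain between them
        clusters = [
            BreakpointCluster(Breakend("chr1", 40_003, "+"), Breakend("chr1", 70_000, "+"), 10),
            BreakpointCluster(Breakend("chr1", 40_006, "-"), Breakend("chr1", 70_001, "-"), 10),
        ]
        g = build_graph_structure([self.interval()], clusters)
        lengths = sorted(e.length for e in g.sequence_edges)
        assert lengths[0] > 100  # no sliver
        assert len(g.sequence_edges) == 3
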