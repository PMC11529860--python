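import json

import numpy as np
import pytest

from ecrecon.model import check_balance
from ecrecon.simulate import (
    MECHANISMS,
    ReadSimConfig,
    SyntheticReference,
    make_test_dataset,
    simulate_alignments,
    simulate_structure,
    truth_cnv_segments,
)

REF = SyntheticReference({"chr1": 1_500_000, "chr2": 1_500_000})


class TestSimulateStructure:
    def test_plain_episomal_excision(self):
        rng = np.random.default_rng(0)
        amp = simulate_structure(REF, "episomal", 1, rng)
        assert len(amp.cycle) == 1
        assert amp.n_breakpoints == 1
        g = amp.true_graph
        assert len(g.sequence_edges) == 1
        assert len(g.discordant_edges) == 1  # the circularizing junction

    def test_chromothripsis_junction_count_tracks_retained_fragments(self):
        rng = np.random.default_rng(1)
        amp = simulate_structure(REF, "chromothripsis", 6, rng)
        assert 2 <= amp.n_breakpoints <= 6
        assert amp.n_breakpoints == len(amp.true_graph.discordant_edges) or any(
            e.cn > amp.copy_number for e in amp.true_graph.discordant_edges
        )

    def test_two_foldback_contains_foldback_edges(self):
        rng = np.random.default_rng(2)
        amp = simulate_structure(REF, "2-foldback", 2, rng)
        foldbacks = [e for e in amp.true_graph.discordant_edges if e.is_foldback]
        assert len(foldbacks) >= 1

    @pytest.mark.parametrize("mechanism", MECHANISMS)
    @pytest.mark.parametrize("nb", [1, 5, 12])
    def test_truth_graph_balanced_by_construction(self, mechanism, nb):
        if mechanism == "chromothripsis" and nb == 1:
            nb = 2
        rng = np.random.default_rng(nb)
        amp = simulate_structure(REF, mechanism, nb, rng)
        assert check_balance(amp.true_graph, 1e-9) == []

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_structure(REF, "episomal", 0, rng)
        with pytest.raises(ValueError):
            simulate_structure(REF, "episomal", 21, rng)
        with pytest.raises(ValueError):
            simulate_structure(REF, "budding", 3, rng)


class TestSimulateAlignments:
    def test_amplicon_coverage_close_to_target(self, tmp_path):
        rng = np.random.default_rng(3)
        amp = simulate_structure(REF, "episomal", 1, rng, chrom="chr1", interval_length=150_000)
        cfg = ReadSimConfig(amplicon_coverage=50.0, background_coverage=13.0)
        bam = simulate_alignments(amp, REF, cfg, rng, tmp_path / "a")
        import pysam

        af = pysam.AlignmentFile(bam)
        chrom, s, e = amp.span
        mid_s, mid_e = s + 30_000, s + 60_000
        total = 0
        for rec in af.fetch(chrom, mid_s, mid_e):
            if rec.is_secondary:
                continue
            total += min(rec.reference_end, mid_e) - max(rec.reference_start, mid_s)
        depth = total / (mid_e - mid_s)
        expected = 50.0 + 13.0
        # within 3 standard errors of the per-window mean at this read length
        assert abs(depth - expected) < 0.25 * expected

    def test_junction_crossing_read_count(self, tmp_path):
        # expected crossings ~= amplicon coverage x (1 - small anchor/FN loss)
        rng = np.random.default_rng(4)
        amp = simulate_structure(REF, "episomal", 1, rng, chrom="chr1", interval_length=150_000)
        cfg = ReadSimConfig(amplicon_coverage=50.0)
        bam = simulate_alignments(amp, REF, cfg, rng, tmp_path / "b")
        from ecrecon.io import AlignmentSource, chain_junctions

        with AlignmentSource(bam) as aln:
            chrom, s, e = amp.span
            chains = aln.chimeric_chains(chrom, s, e)
        crossings = sum(len(chain_junctions(c)) for c in chains)
        assert 0.7 * 50 < crossings < 1.3 * 50

    def test_zero_amplicon_coverage_gives_no_chimeras(self, tmp_path):
        rng = np.random.default_rng(5)
        amp = simulate_structure(REF, "episomal", 1, rng, chrom="chr1")
        cfg = ReadSimConfig(amplicon_coverage=0.0)
        bam = simulate_alignments(amp, REF, cfg, rng, tmp_path / "c")
        from ecrecon.io import AlignmentSource

        with AlignmentSource(bam) as aln:
            chrom, s, e = amp.span
            assert aln.chimeric_chains(chrom, s, e) == []

    def test_reads_inside_one_segment_are_single_records(self, tmp_path):
        rng = np.random.default_rng(6)
        amp = simulate_structure(REF, "episomal", 1, rng, chrom="chr1")
        cfg = ReadSimConfig(amplicon_coverage=10.0)
        bam = simulate_alignments(amp, REF, cfg, rng, tmp_path / "d")
        import pysam

        af = pysam.AlignmentFile(bam)
        chrom, s, e = amp.span
        interior = [
            r
            for r in af.fetch(chrom, s + 20_000, s + 30_000)
            if not r.is_supplementary and not r.has_tag("SA")
        ]
        assert interior  # plenty of whole-segment and background reads
        assert all("S" not in (r.cigarstring or "") for r in interior)


class TestMakeTestDataset:
    def test_determinism_under_fixed_seed(self, tmp_path):
        import hashlib

        def run(sub):
            rng = np.random.default_rng(42)
            pool = [
                simulate_structure(REF, "episomal", 2, rng, chrom="chr1"),
                simulate_structure(REF, "2-foldback", 3, rng, chrom="chr2"),
            ]
            ds = make_test_dataset(pool, 2, 50.0, rng, tmp_path / sub, reference=REF)
            manifest = json.load(open(ds.manifest_path))
            digest = hashlib.sha256()
            import pysam

            for rec in pysam.AlignmentFile(ds.bam_path):
                digest.update(rec.to_string().encode())
            return manifest, digest.hexdigest()

        m1, d1 = run("r1")
        m2, d2 = run("r2")
        assert m1 == m2
        assert d1 == d2

    def test_single_amplicon_truth_record(self, episomal_dataset):
        assert len(episomal_dataset.amplicons) == 1
        assert len(episomal_dataset.truth_graph_paths) == 1
        manifest = json.load(open(episomal_dataset.manifest_path))
        assert manifest["amplicons"][0]["mechanism"] == "episomal"

    def test_overlapping_source_regions_rejected(self, tmp_path):
        rng = np.random.default_rng(8)
        a1 = simulate_structure(REF, "episomal", 1, rng, chrom="chr1")
        rng2 = np.random.default_rng(8)
        a2 = simulate_structure(REF, "episomal", 1, rng2, chrom="chr1")
        with pytest.raises(ValueError, match="overlap"):
            make_test_dataset([a1, a2], 2, 50.0, np.random.default_rng(0), tmp_path / "x", reference=REF)

    def test_truth_cnv_table_covers_genome(self):
        rng = np.random.default_rng(9)
        amp = simulate_structure(REF, "episomal", 2, rng, chrom="chr1")
        segs = truth_cnv_segments([amp], REF, ReadSimConfig())
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, length in REF.lengths.items():
            ss = sorted(by_chrom[chrom], key=lambda s: s.start)
            assert ss[0].start == 1 and ss[-1].end == length
            for a, b in zip(ss, ss[1:]):
                assert b.start == a.end + 1
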