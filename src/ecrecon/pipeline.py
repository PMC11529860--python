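"""End-to-end reconstruction driver: seeds -> intervals -> graph -> CN -> cycles."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

from .cnfit import CoverageModel, assign_cn, estimate_theta
from .cycles import (
    Decomposition,
    ExtractionConfig,
    SubwalkConstraint,
    estimate_multiplicity_caps,
    extract_cycles,
    extract_subwalk_constraints,
)
from .intervals import (
    AmplifiedInterval,
    SearchConfig,
    bfs_interval_search,
    build_graph_structure,
    cluster_breakpoints,
    merge_intervals,
    populate_observations,
    select_seeds,
)
from .io import AlignmentSource, chain_junctions, read_cnv_calls, write_cycles, write_graph
from .model import BreakpointGraph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AmpliconResult", "reconstruct", "walks_to_cycle_records"]


@dataclass
class RunConfig:
    """Full pipeline configuration; serialized next to the outputs."""

    search: SearchConfig = field(default_factory=SearchConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    stage: str = "cycles"  # "graph" stops after CN assignment
    sample: str = "sample"

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "search": asdict(self.search),
                    "extraction": asdict(self.extraction),
                    "stage": self.stage,
                    "sample": self.sample,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


@dataclass
class AmpliconResult:
    amplicon_id: int
    intervals: list[AmplifiedInterval]
    graph: BreakpointGraph
    constraints: list[SubwalkConstraint]
    decomposition: Decomposition | None
    graph_path: str | None = None
    cycles_path: str | None = None


def _amplicon_clusters(alignments, intervals, config: SearchConfig, theta: float):
    """Re-search breakpoints across the merged intervals of one amplicon:
    every chimeric read is counted once, junctions must have both breakends
    inside the amplicon's intervals."""
    from .intervals import canonical_pair, is_concordant_pair

    seen: set[str] = set()
    pairs = []
    n_outside = 0
    for iv in intervals:
        for chain in alignments.chimeric_chains(iv.chrom, iv.start, iv.end):
            qname = chain[0].qname
            if qname in seen:
                continue
            seen.add(qname)
            for a, b in chain_junctions(chain):
                if is_concordant_pair(a, b):
                    continue
                in_a = any(v.contains(a.chrom, a.position) for v in intervals)
                in_b = any(v.contains(b.chrom, b.position) for v in intervals)
                if in_a and in_b:
                    pairs.append(canonical_pair(a, b))
                elif in_a or in_b:
                    n_outside += 1
    if n_outside:
        logger.warning(
            "%d junction observations left the amplicon's intervals (discarded)",
            n_outside,
        )
    clusters = cluster_breakpoints(pairs, config.cluster_window, config.min_cluster_support(theta))
    kept = [c for c in clusters if not c.low_confidence]
    for c in clusters:
        if c.low_confidence:
            logger.info(
                "discarding low-support cluster %s->%s (%d reads)",
                c.breakend_a,
                c.breakend_b,
                c.support,
            )
    return kept


def reconstruct(
    bam_path,
    cnv_path,
    config: RunConfig | None = None,
    out_dir=None,
) -> list[AmpliconResult]:
    """Run the reconstruction pipeline and (optionally) write per-amplicon
    graph and cycles files named ``<sample>_amplicon<k>_{graph,cycles}.txt``."""
    config = config or RunConfig()
    t0 = time.time()
    segments = read_cnv_calls(cnv_path)
    theta = estimate_theta(segments)
    logger.info("estimated diploid coverage theta = %.2f", theta)
    results: list[AmpliconResult] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        config.dump(os.path.join(out_dir, f"{config.sample}_config.json"))
    with AlignmentSource(bam_path) as aln:
        seeds = select_seeds(segments, config.search)
        logger.info("%d seed interval(s)", len(seeds))
        if not seeds:
            return results
        intervals, connections = bfs_interval_search(
            seeds, aln, segments, config.search, theta
        )
        intervals, connections = merge_intervals(
            intervals, connections, config.search.delta
        )
        by_amp: dict[int, list[AmplifiedInterval]] = {}
        for iv in intervals:
            by_amp.setdefault(iv.amplicon_id, []).append(iv)
        for amp_id in sorted(by_amp):
            ivs = by_amp[amp_id]
            logger.info(
                "amplicon %d: %d interval(s) spanning %s",
                amp_id,
                len(ivs),
                ", ".join(f"{v.chrom}:{v.start}-{v.end}" for v in ivs),
            )
            clusters = _amplicon_clusters(aln, ivs, config.search, theta)
            graph = build_graph_structure(ivs, clusters, amplicon_id=amp_id)
            populate_observations(graph, aln)
            assign_cn(graph, CoverageModel(theta))
            estimate_multiplicity_caps(graph)
            constraints: list[SubwalkConstraint] = []
            decomp = None
            if config.stage == "cycles":
                constraints = extract_subwalk_constraints(
                    aln, graph, window=config.search.cluster_window
                )
                decomp = extract_cycles(graph, constraints, config.extraction)
            result = AmpliconResult(amp_id, ivs, graph, constraints, decomp)
            if out_dir:
                gp = os.path.join(out_dir, f"{config.sample}_amplicon{amp_id}_graph.txt")
                write_graph(graph, gp)
                result.graph_path = gp
                if decomp is not None:
                    cp = os.path.join(
                        out_dir, f"{config.sample}_amplicon{amp_id}_cycles.txt"
                    )
                    write_cycles(walks_to_cycle_records(decomp), cp)
                    result.cycles_path = cp
            results.append(result)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return results


def walks_to_cycle_records(decomp: Decomposition):
    from .io import CycleRecord

    records = []
    for i, walk in enumerate(decomp.walks, start=1):
        records.append(
            CycleRecord(
                index=i,
                copy_number=walk.copy_number,
                is_cycle=walk.is_cycle,
                segments=_canonical_segments(walk),
            )
        )
    return records


def _canonical_segments(walk):
    """Rotate a cycle to start at its smallest coordinate, oriented so the
    first segment reads forward, for stable downstream comparison."""
    segs = walk.oriented_segments()
    if not segs or not walk.is_cycle:
        return segs
    variants = []
    flipped = [
        (c, s, e, "+" if o == "-" else "-") for c, s, e, o in reversed(segs)
    ]
    for seq in (segs, flipped):
        for i in range(len(seq)):
            variants.append(seq[i:] + seq[:i])
    return min(variants, key=lambda v: ([(c, s, e, 0 if o == "+" else 1) for c, s, e, o in v]))
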