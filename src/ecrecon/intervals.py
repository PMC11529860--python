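"""Seed selection and breadth-first discovery of amplified intervals.

From whole-genome CNV calls we pick focally amplified *seed intervals*
(runs of adjacent high-CN segments above an aggregate-size threshold), then
follow discordant junctions evidenced by chimeric long-read alignments to
collect every amplified interval reachable from a seed.  Connected intervals
form an *amplicon*; each amplicon is turned into a structured breakpoint
graph (copy numbers are assigned later by :mod:`ecrecon.cnfit`).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from statistics import median

from .model import (
    Breakend,
    BreakpointGraph,
    ConcordantEdge,
    DiscordantEdge,
    SequenceEdge,
    SourceEdge,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CNVSegment",
    "AmplifiedInterval",
    "BreakpointCluster",
    "IntervalConnection",
    "SearchConfig",
    "select_seeds",
    "extract_chimeric_breakpoints",
    "cluster_breakpoints",
    "bfs_interval_search",
    "merge_intervals",
    "build_graph_structure",
    "populate_observations",
]


@dataclass(frozen=True)
class CNVSegment:
    """A called copy-number segment (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    cn: float
    mean_coverage: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AmplifiedInterval:
    """A genomic interval participating in an amplicon."""

    chrom: str
    start: int
    end: int
    visited: bool = False
    amplicon_id: int = -1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


BreakendPair = tuple[Breakend, Breakend]


def canonical_pair(a: Breakend, b: Breakend) -> BreakendPair:
    return (a, b) if a <= b else (b, a)


def is_concordant_pair(a: Breakend, b: Breakend) -> bool:
    """True when the junction is a plain reference adjacency."""
    a, b = canonical_pair(a, b)
    return (
        a.chrom == b.chrom
        and a.orientation == "+"
        and b.orientation == "-"
        and b.position - a.position == 1
    )


@dataclass
class BreakpointCluster:
    """A greedy cluster of near-identical junction breakend pairs."""

    breakend_a: Breakend
    breakend_b: Breakend
    support: int
    low_confidence: bool = False
    positions_a: list[int] = field(default_factory=list)
    positions_b: list[int] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.breakend_a, self.breakend_b)


@dataclass
class IntervalConnection:
    """A pair of amplified intervals joined by >= 1 breakpoint cluster."""

    interval_a: AmplifiedInterval
    interval_b: AmplifiedInterval
    labels: list[BreakpointCluster] = field(default_factory=list)


@dataclass
class SearchConfig:
    """Tunables of the interval search.

    ``delta`` pads new intervals; ``big_delta`` caps how far an amplified CNV
    segment is followed from the junction locus.  ``min_support_floor`` is
    the lower bound on cluster read support; the operational threshold is
    ``max(floor, round(theta / 2))`` (half the diploid coverage, i.e. the
    haploid coverage).
    """

    seed_cn_min: float = 5.0
    seed_size_min: int = 50_000
    seed_gap_max: int = 100_000
    delta: int = 100_000
    big_delta: int = 2_000_000
    cluster_window: int = 100
    min_support_floor: int = 3

    def __post_init__(self) -> None:
        for name in (
            "seed_cn_min",
            "seed_size_min",
            "seed_gap_max",
            "delta",
            "big_delta",
            "cluster_window",
            "min_support_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_cluster_support(self, theta: float) -> int:
        return max(self.min_support_floor, int(round(theta / 2.0)))


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------


def select_seeds(segments: list[CNVSegment], config: SearchConfig) -> list[AmplifiedInterval]:
    """Maximal runs of amplified CNV segments (``cn >= seed_cn_min``) whose
    aggregate amplified length reaches ``seed_size_min``, one interval per
    run.  Unamplified gaps up to ``seed_gap_max`` bp do not break a run
    (focal amplifications such as chromothripsis-derived ecDNA present as
    interleaved high/low CN segments); only the amplified bases count toward
    the aggregate size, and the emitted seed spans the whole run."""
    seeds: list[AmplifiedInterval] = []
    run: list[CNVSegment] = []

    def flush() -> None:
        if run and sum(s.length for s in run) >= config.seed_size_min:
            seeds.append(AmplifiedInterval(run[0].chrom, run[0].start, run[-1].end))
        run.clear()

    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    for seg in ordered:
        if seg.cn >= config.seed_cn_min:
            if run and not (
                seg.chrom == run[-1].chrom
                and seg.start - run[-1].end - 1 <= config.seed_gap_max
            ):
                flush()
            run.append(seg)
        else:
            continue
    flush()
    return seeds


# ---------------------------------------------------------------------------
# Breakpoint extraction and clustering
# ---------------------------------------------------------------------------


def extract_chimeric_breakpoints(alignments, interval: AmplifiedInterval) -> list[BreakendPair]:
    """Breakend pairs, one per split junction, of chimeric reads with a
    fragment inside *interval*.  Junctions with neither breakend in the
    interval are skipped; reference-adjacent (concordant) splits are ignored.
    """
    from .io import chain_junctions

    pairs: list[BreakendPair] = []
    for chain in alignments.chimeric_chains(interval.chrom, interval.start, interval.end):
        for a, b in chain_junctions(chain):
            if is_concordant_pair(a, b):
                continue
            if interval.contains(a.chrom, a.position) or interval.contains(b.chrom, b.position):
                pairs.append(canonical_pair(a, b))
    return pairs


def cluster_breakpoints(
    raw: list[BreakendPair], window: int, min_support: int
) -> list[BreakpointCluster]:
    """Greedy agglomeration of canonicalized breakend pairs.

    Pairs are grouped by (chrom, orientation) signature and swept in sorted
    position order; a new cluster starts whenever either breakend strays more
    than *window* bp from the current cluster representative (the member
    median).  Clusters below *min_support* are flagged low-confidence.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_sig: dict[tuple, list[BreakendPair]] = {}
    for a, b in raw:
        a, b = canonical_pair(a, b)
        by_sig.setdefault((a.chrom, a.orientation, b.chrom, b.orientation), []).append((a, b))

    clusters: list[BreakpointCluster] = []
    for (ca, oa, cb, ob), pairs in sorted(by_sig.items()):
        pairs.sort(key=lambda p: (p[0].position, p[1].position))
        cur: BreakpointCluster | None = None
        for a, b in pairs:
            if cur is not None:
                rep_a, rep_b = cur.breakend_a.position, cur.breakend_b.position
                if abs(a.position - rep_a) <= window and abs(b.position - rep_b) <= window:
                    cur.positions_a.append(a.position)
                    cur.positions_b.append(b.position)
                    cur.support += 1
                    cur.breakend_a = Breakend(ca, int(median(cur.positions_a)), oa)
                    cur.breakend_b = Breakend(cb, int(median(cur.positions_b)), ob)
                    continue
            cur = BreakpointCluster(a, b, 1, positions_a=[a.position], positions_b=[b.position])
            clusters.append(cur)
    for c in clusters:
        c.low_confidence = c.support < min_support
        if c.low_confidence:
            logger.debug("low-support cluster %s->%s (%d reads)", c.breakend_a, c.breakend_b, c.support)
    clusters.sort(key=lambda c: c.key())
    return clusters


def _same_junction(c: BreakpointCluster, d: BreakpointCluster, window: int) -> bool:
    a1, b1 = c.breakend_a, c.breakend_b
    a2, b2 = d.breakend_a, d.breakend_b
    return (
        a1.chrom == a2.chrom
        and b1.chrom == b2.chrom
        and a1.orientation == a2.orientation
        and b1.orientation == b2.orientation
        and abs(a1.position - a2.position) <= window
        and abs(b1.position - b2.position) <= window
    )


# ---------------------------------------------------------------------------
# BFS interval search
# ---------------------------------------------------------------------------


def _clamp_interval(chrom: str, start: int, end: int, chrom_lengths: dict[str, int]):
    length = chrom_lengths.get(chrom)
    start = max(1, start)
    if length is not None:
        end = min(end, length)
    return AmplifiedInterval(chrom, start, end)


def _find(intervals: list[AmplifiedInterval], chrom: str, pos: int):
    for iv in intervals:
        if iv.contains(chrom, pos):
            return iv
    return None


def bfs_interval_search(
    seeds: list[AmplifiedInterval],
    alignments,
    segments: list[CNVSegment],
    config: SearchConfig,
    theta: float,
) -> tuple[list[AmplifiedInterval], list[IntervalConnection]]:
    """Discover all amplified intervals connected to *seeds* and the labeled
    connections between them.

    Seeds are padded by ``delta`` (clamped to chromosome bounds) before the
    search so junction breakends near a seed boundary stay inside an
    interval.  Clusters are explored in descending support order (ties by
    coordinate) and must reach haploid-coverage support.
    """
    if not seeds:
        raise ValueError("no seed intervals")
    chrom_lengths = alignments.references
    min_support = config.min_cluster_support(theta)

    intervals: list[AmplifiedInterval] = [
        _clamp_interval(s.chrom, s.start - config.delta, s.end + config.delta, chrom_lengths)
        for s in seeds
    ]
    connections: dict[tuple, IntervalConnection] = {}

    def connect(a: AmplifiedInterval, b: AmplifiedInterval, cluster: BreakpointCluster) -> None:
        ia, ib = intervals.index(a), intervals.index(b)
        key = (min(ia, ib), max(ia, ib))
        conn = connections.setdefault(
            key, IntervalConnection(intervals[key[0]], intervals[key[1]])
        )
        if not any(_same_junction(cluster, lab, config.cluster_window) for lab in conn.labels):
            conn.labels.append(cluster)

    for start_iv in intervals:
        if start_iv.visited:
            continue
        queue: deque[AmplifiedInterval] = deque([start_iv])
        start_iv.visited = True
        while queue:
            a0 = queue.popleft()
            try:
                raw = extract_chimeric_breakpoints(alignments, a0)
            except (OSError, ValueError) as exc:
                raise OSError(
                    f"alignment fetch failed for {a0.chrom}:{a0.start}-{a0.end}: {exc}"
                ) from exc
            clusters = cluster_breakpoints(raw, config.cluster_window, min_support)
            clusters.sort(key=lambda c: (-c.support, c.key()))
            for cluster in clusters:
                if cluster.low_confidence:
                    continue
                for bnd, other in (
                    (cluster.breakend_a, cluster.breakend_b),
                    (cluster.breakend_b, cluster.breakend_a),
                ):
                    if not a0.contains(bnd.chrom, bnd.position):
                        continue
                    target = _find(intervals, other.chrom, other.position)
                    if target is not None:
                        connect(a0, target, cluster)
                        if not target.visited:
                            target.visited = True
                            queue.append(target)
                        continue
                    seg = next(
                        (
                            s
                            for s in segments
                            if s.chrom == other.chrom
                            and s.start <= other.position <= s.end
                            and s.cn >= config.seed_cn_min
                        ),
                        None,
                    )
                    l = other.position
                    if seg is not None:
                        new = _clamp_interval(
                            other.chrom,
                            max(seg.start - config.delta, l - config.big_delta),
                            min(seg.end + config.delta, l + config.big_delta),
                            chrom_lengths,
                        )
                    else:
                        new = _clamp_interval(
                            other.chrom, l - config.delta, l + config.delta, chrom_lengths
                        )
                    new.visited = True
                    intervals.append(new)
                    queue.append(new)
                    connect(a0, new, cluster)
    return intervals, list(connections.values())


# ---------------------------------------------------------------------------
# Interval merging and amplicon assignment
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: list[AmplifiedInterval],
    connections: list[IntervalConnection],
    delta: int,
) -> tuple[list[AmplifiedInterval], list[IntervalConnection]]:
    """Merge (1) overlapping or coordinate-adjacent intervals and (2)
    same-chromosome intervals within ``2 * delta`` that share a breakpoint
    connection; relabel connections and assign amplicon ids by connectivity.
    """
    parent = list(range(len(intervals)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    connected = {
        frozenset((intervals.index(c.interval_a), intervals.index(c.interval_b)))
        for c in connections
    }
    n = len(intervals)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            gap = hi.start - lo.end - 1
            if gap <= 0:
                union(i, j)
            elif gap <= 2 * delta and frozenset((i, j)) in connected:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[AmplifiedInterval] = []
    index_map: dict[int, int] = {}
    for members in groups.values():
        chrom = intervals[members[0]].chrom
        iv = AmplifiedInterval(
            chrom,
            min(intervals[i].start for i in members),
            max(intervals[i].end for i in members),
            visited=True,
        )
        for i in members:
            index_map[i] = len(merged)
        merged.append(iv)
    merged_order = sorted(range(len(merged)), key=lambda k: merged[k].key())
    rank = {old: new for new, old in enumerate(merged_order)}
    merged = [merged[i] for i in merged_order]
    index_map = {i: rank[m] for i, m in index_map.items()}

    new_conns: dict[tuple, IntervalConnection] = {}
    for conn in connections:
        ia = index_map[intervals.index(conn.interval_a)]
        ib = index_map[intervals.index(conn.interval_b)]
        key = (min(ia, ib), max(ia, ib))
        target = new_conns.setdefault(key, IntervalConnection(merged[key[0]], merged[key[1]]))
        for lab in conn.labels:
            if not any(_same_junction(lab, x, delta) for x in target.labels):
                target.labels.append(lab)

    # amplicon ids: connected components of merged intervals via connections
    comp = list(range(len(merged)))

    def cfind(i: int) -> int:
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for (ia, ib) in new_conns:
        comp[cfind(ia)] = cfind(ib)
    amp_ids: dict[int, int] = {}
    for i, iv in enumerate(merged):
        root = cfind(i)
        amp_ids.setdefault(root, len(amp_ids) + 1)
        iv.amplicon_id = amp_ids[root]
    return merged, list(new_conns.values())


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------


def _snap_cuts(clusters: list[BreakpointCluster], window: int) -> dict[str, set[int]]:
    """Segment-boundary positions implied by the cluster breakends, with
    nearby cuts merged to a support-weighted consensus.

    The two breakends of an inversion land on opposite sides of (nearly) the
    same boundary; without snapping, breakend placement noise leaves tiny
    sliver segments between them whose nodes carry no junction, which skews
    the balance constraints.  Breakend positions are rewritten in place to
    agree with the consensus cuts.
    """
    # cut c = boundary between positions c and c+1
    raw: dict[str, list[tuple[int, int, BreakpointCluster, str]]] = {}
    for cluster in clusters:
        for which in ("a", "b"):
            bnd = getattr(cluster, f"breakend_{which}")
            cut = bnd.position if bnd.orientation == "+" else bnd.position - 1
            raw.setdefault(bnd.chrom, []).append((cut, cluster.support, cluster, which))
    cuts: dict[str, set[int]] = {}
    for chrom, items in raw.items():
        items.sort(key=lambda t: t[0])
        group: list[tuple[int, int, BreakpointCluster, str]] = []

        def flush() -> None:
            if not group:
                return
            positions = [c for c, s, _, _ in group for _ in range(s)]
            consensus = int(median(positions))
            cuts.setdefault(chrom, set()).add(consensus)
            for _, _, cluster, which in group:
                bnd = getattr(cluster, f"breakend_{which}")
                pos = consensus if bnd.orientation == "+" else consensus + 1
                setattr(cluster, f"breakend_{which}", Breakend(bnd.chrom, pos, bnd.orientation))
            group.clear()

        for item in items:
            if group and item[0] - group[-1][0] > window:
                flush()
            group.append(item)
        flush()
    return cuts


def build_graph_structure(
    intervals: list[AmplifiedInterval],
    clusters: list[BreakpointCluster],
    amplicon_id: int = 1,
    cut_merge_window: int = 50,
) -> BreakpointGraph:
    """Assemble the breakpoint graph (structure only, CN unset) of one
    amplicon from its merged intervals and retained breakpoint clusters.

    Sequence edges exactly tile every interval, split at each cluster
    breakend (nearby cuts snapped to a consensus boundary); concordant edges
    join reference-adjacent sequence edges; source edges attach ``s`` at
    each interval's smallest coordinate and ``t`` at its largest.
    """
    graph = BreakpointGraph(amplicon_id=amplicon_id)
    for cluster in clusters:
        for bnd in (cluster.breakend_a, cluster.breakend_b):
            if _find(intervals, bnd.chrom, bnd.position) is None:
                raise ValueError(
                    f"cluster breakend {bnd} outside all amplified intervals "
                    "(interval search missed a locus)"
                )
    cuts = _snap_cuts(clusters, cut_merge_window)

    for iv in sorted(intervals, key=lambda v: v.key()):
        inner = sorted(
            c for c in cuts.get(iv.chrom, ()) if iv.start <= c < iv.end
        )
        bounds = [iv.start - 1, *inner, iv.end]
        for left, right in zip(bounds, bounds[1:]):
            graph.add(SequenceEdge(iv.chrom, left + 1, right))
        for cut in inner:
            graph.add(ConcordantEdge(iv.chrom, cut))
        graph.add(SourceEdge("s", Breakend(iv.chrom, iv.start, "-")))
        graph.add(SourceEdge("t", Breakend(iv.chrom, iv.end, "+")))

    seen: dict[tuple, DiscordantEdge] = {}
    for cluster in clusters:
        try:
            edge = DiscordantEdge(
                cluster.breakend_a, cluster.breakend_b, read_support=cluster.support
            )
        except ValueError:
            logger.warning(
                "cluster %s->%s became reference-adjacent after cut snapping; dropped",
                cluster.breakend_a,
                cluster.breakend_b,
            )
            continue
        if edge.key() in seen:
            seen[edge.key()].read_support += cluster.support
            continue
        seen[edge.key()] = edge
        graph.add(edge)
    graph.sort()
    graph.validate()
    return graph


def populate_observations(graph: BreakpointGraph, alignments, read_through_margin: int = 50) -> None:
    """Fill observed nucleotide totals (sequence edges) and read-through
    support counts (concordant edges) from the alignments.

    A fragment supports a concordant edge only when it extends at least
    ``read_through_margin`` bp on both sides of the junction, so breakend
    placement noise on split reads does not masquerade as read-through.
    """
    for e in graph.sequence_edges:
        total = 0
        for frag in alignments.fetch_fragments(e.chrom, e.start, e.end):
            total += min(frag.ref_end, e.end) - max(frag.ref_start, e.start) + 1
        e.observed_nucleotides = float(total)
    for e in graph.concordant_edges:
        p = e.left_position
        m = read_through_margin
        e.read_support = sum(
            1
            for frag in alignments.fetch_fragments(e.chrom, p, p + 1)
            if frag.ref_start <= p - m + 1 and frag.ref_end >= p + m
        )
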