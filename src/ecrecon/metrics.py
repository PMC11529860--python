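"""Reconstruction-quality measures for (truth, reconstruction) pairs.

Four measures compare a true cycle W_t / graph G_t against a reconstructed
cycle W_r / graph G_r:

* **breakpoint_graph_accuracy** — fraction of true discordant edges with a
  one-to-one match (both breakends within tolerance, orientations equal) in
  the reconstruction;
* **cycle_interval_overlap** — nucleotide-weighted Jaccard index of the
  genomic intervals covered by the two cycles (multiplicity ignored);
* **cyclic_lcs** — longest common subsequence of oriented segment tokens
  after eliminating segments not present in both cycles, maximized over
  rotations and orientation flips (cycles have no canonical start or
  strand), normalized to the nucleotide length of W_t;
* **length_error** — log2 of the relative amplicon-length difference, with
  a small floor guarding the exact-match case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx

from .io import CycleRecord
from .model import BreakpointGraph

__all__ = [
    "EvaluationReport",
    "LengthError",
    "breakpoint_graph_accuracy",
    "cycle_interval_overlap",
    "cyclic_lcs",
    "length_error",
    "evaluate_pair",
    "LENGTH_ERROR_FLOOR",
]

LENGTH_ERROR_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Breakpoint-graph accuracy
# ---------------------------------------------------------------------------


def _edges_match(e_t, e_r, tolerance: int) -> bool:
    for a, b in (
        (e_r.breakend_a, e_r.breakend_b),
        (e_r.breakend_b, e_r.breakend_a),
    ):
        ta, tb = e_t.breakend_a, e_t.breakend_b
        if (
            ta.chrom == a.chrom
            and tb.chrom == b.chrom
            and ta.orientation == a.orientation
            and tb.orientation == b.orientation
            and abs(ta.position - a.position) <= tolerance
            and abs(tb.position - b.position) <= tolerance
        ):
            return True
    return False


def breakpoint_graph_accuracy(
    truth: BreakpointGraph, recon: BreakpointGraph, tolerance: int = 100
) -> float:
    """Proportion of truth discordant edges matched one-to-one (maximum
    bipartite matching) by reconstructed discordant edges within
    *tolerance* bp and with matching orientations."""
    t_edges = truth.discordant_edges
    r_edges = recon.discordant_edges
    if not t_edges:
        return 1.0
    g = nx.Graph()
    left = [("t", i) for i in range(len(t_edges))]
    g.add_nodes_from(left, bipartite=0)
    g.add_nodes_from((("r", j) for j in range(len(r_edges))), bipartite=1)
    for i, et in enumerate(t_edges):
        for j, er in enumerate(r_edges):
            if _edges_match(et, er, tolerance):
                g.add_edge(("t", i), ("r", j))
    matching = nx.algorithms.bipartite.hopcroft_karp_matching(g, top_nodes=left)
    matched = sum(1 for node in matching if node[0] == "t")
    return matched / len(t_edges)


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------


def _merged_intervals(cycle: CycleRecord) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _ in cycle.segments:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(iv) for iv in merged]
    return out


def cycle_interval_overlap(truth: CycleRecord, recon: CycleRecord) -> float:
    """Nucleotide-weighted Jaccard index of the reference intervals covered
    by the two cycles (segment order and multiplicity ignored)."""
    t_iv, r_iv = _merged_intervals(truth), _merged_intervals(recon)
    inter = union = 0
    for chrom in set(t_iv) | set(r_iv):
        tv = t_iv.get(chrom, [])
        rv = r_iv.get(chrom, [])
        union += sum(e - s + 1 for s, e in tv) + sum(e - s + 1 for s, e in rv)
        for s1, e1 in tv:
            for s2, e2 in rv:
                ov = min(e1, e2) - max(s1, s2) + 1
                if ov > 0:
                    inter += ov
    union -= inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Cyclic LCS
# ---------------------------------------------------------------------------


def _match_tokens(truth: CycleRecord, recon: CycleRecord, tolerance: int):
    """Assign a shared token id to each truth segment and to each recon
    segment whose endpoints both lie within *tolerance* of it; returns the
    two token sequences (id, orientation) restricted to shared segments,
    plus per-token nucleotide lengths."""
    t_keys = []
    seen: dict[tuple, int] = {}
    for chrom, s, e, _ in truth.segments:
        key = (chrom, s, e)
        if key not in seen:
            seen[key] = len(seen)
        t_keys.append(seen[key])
    lengths = {tid: key[2] - key[1] + 1 for key, tid in seen.items()}

    def recon_token(seg):
        chrom, s, e, _ = seg
        best_tid, best_d = None, None
        for (tc, ts, te), tid in sorted(seen.items(), key=lambda kv: kv[0]):
            if tc != chrom:
                continue
            d = max(abs(ts - s), abs(te - e))
            if d <= tolerance and (best_d is None or d < best_d):
                best_tid, best_d = tid, d
        return best_tid

    r_tokens_all = [(recon_token(seg), seg[3]) for seg in recon.segments]
    shared = {tid for tid, _ in r_tokens_all if tid is not None}
    t_seq = [
        (tid, seg[3])
        for tid, seg in zip(t_keys, truth.segments)
        if tid in shared
    ]
    r_seq = [(tid, o) for tid, o in r_tokens_all if tid in shared]
    return t_seq, r_seq, lengths


def _weighted_lcs(a: list, b: list, weight) -> float:
    n, m = len(a), len(b)
    dp = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + weight(a[i - 1])
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[n][m]


def _flip_seq(seq: list) -> list:
    return [(tid, "+" if o == "-" else "-") for tid, o in reversed(seq)]


def cyclic_lcs(
    truth: CycleRecord,
    recon: CycleRecord,
    tolerance: int = 100,
    orientation_sensitive: bool = True,
) -> float:
    """Longest common subsequence of shared oriented segments, maximized
    over all rotations of both cycles and both orientations of the
    reconstruction, normalized by the nucleotide length of the truth cycle."""
    t_seq, r_seq, lengths = _match_tokens(truth, recon, tolerance)
    total = sum(e - s + 1 for _, s, e, _ in truth.segments)
    if not t_seq or not r_seq or total == 0:
        return 0.0
    if not orientation_sensitive:
        t_seq = [(tid, "") for tid, _ in t_seq]
        r_seq = [(tid, "") for tid, _ in r_seq]

    def weight(token):
        return float(lengths[token[0]])

    best = 0.0
    r_variants = [r_seq, _flip_seq(r_seq)] if orientation_sensitive else [r_seq, list(reversed(r_seq))]
    for rv in r_variants:
        for i in range(len(t_seq)):
            t_rot = t_seq[i:] + t_seq[:i]
            for j in range(len(rv)):
                r_rot = rv[j:] + rv[:j]
                best = max(best, _weighted_lcs(t_rot, r_rot, weight))
    return min(best / total, 1.0)


# ---------------------------------------------------------------------------
# Length error
# ---------------------------------------------------------------------------


class LengthError(NamedTuple):
    value: float
    exact_match: bool


def length_error(truth: CycleRecord, recon: CycleRecord) -> LengthError:
    """log2((|len_r - len_t| / len_t) + floor); exact matches report the
    floor value with a flag."""
    import math

    len_t, len_r = truth.length, recon.length
    if len_t <= 0 or len_r <= 0:
        raise ValueError("cycle lengths must be positive")
    rel = abs(len_r - len_t) / len_t
    return LengthError(math.log2(rel + LENGTH_ERROR_FLOOR), rel == 0.0)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    breakpoint_graph_accuracy: float
    cycle_interval_overlap: float
    cyclic_lcs: float
    length_error: float
    exact_length: bool
    heaviest_cycle_weight_ratio: float

    def to_row(self) -> str:
        return "\t".join(
            [
                f"{self.breakpoint_graph_accuracy:.4f}",
                f"{self.cycle_interval_overlap:.4f}",
                f"{self.cyclic_lcs:.4f}",
                f"{self.length_error:.4f}",
                str(int(self.exact_length)),
                f"{self.heaviest_cycle_weight_ratio:.4f}",
            ]
        )

    header = (
        "breakpoint_graph_accuracy\tcycle_interval_overlap\tcyclic_lcs\t"
        "length_error\texact_length\theaviest_cycle_weight_ratio"
    )


def evaluate_pair(
    truth_graph: BreakpointGraph,
    truth_cycle: CycleRecord,
    recon_graph: BreakpointGraph,
    recon_cycles: list[CycleRecord],
    tolerance: int = 100,
) -> EvaluationReport:
    """Score a reconstruction against one truth amplicon.

    Cycle-level measures use the best reconstructed cycle for each measure;
    the heaviest-cycle weight ratio is the fraction of the reconstructed
    graph's length-weighted CN carried by its heaviest cycle."""
    from .model import length_weighted_cn

    acc = breakpoint_graph_accuracy(truth_graph, recon_graph, tolerance)
    cycles = [c for c in recon_cycles if c.is_cycle] or list(recon_cycles)
    if cycles:
        overlap = max(cycle_interval_overlap(truth_cycle, c) for c in cycles)
        lcs = max(cyclic_lcs(truth_cycle, c, tolerance) for c in cycles)
        err = min((length_error(truth_cycle, c) for c in cycles), key=lambda le: le.value)
        cl = length_weighted_cn(recon_graph)
        heaviest = max(c.copy_number * c.length for c in cycles)
        ratio = min(heaviest / cl, 1.0) if cl > 0 else 0.0
    else:
        overlap = lcs = ratio = 0.0
        err = LengthError(float("inf"), False)
    return EvaluationReport(
        breakpoint_graph_accuracy=acc,
        cycle_interval_overlap=overlap,
        cyclic_lcs=lcs,
        length_error=err.value,
        exact_length=err.exact_match,
        heaviest_cycle_weight_ratio=ratio,
    )
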