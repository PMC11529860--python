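"""Brute-force decomposition oracle for tiny breakpoint graphs.

Independent of the MILP path: candidate walks are enumerated by a direct
DFS over alternating trails (bounded by the same per-edge caps), weights
are optimized with a plain LP per support subset, and the full-mode
objective  #walks - mass/Cl - satisfied/m  is minimized by exhaustive
search over subsets of at most ``max_walks`` walk supports.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog

from ecrecon.cycles import ExtractionConfig, edge_caps
from ecrecon.model import length_weighted_cn


def _edge_info(graph, config):
    caps = edge_caps(graph, config)
    info = []
    for e in graph.sequence_edges:
        info.append((e.key(), "seq", e.nodes(), e.cn, e.length, caps[e.key()], False))
    for e in graph.concordant_edges:
        info.append((e.key(), "bp", e.nodes(), e.cn, 0, caps[e.key()], False))
    for e in graph.discordant_edges:
        info.append((e.key(), "bp", e.nodes(), e.cn, 0, caps[e.key()], e.is_foldback))
    for e in graph.source_edges:
        info.append((e.key(), "bp", e.nodes(), e.cn, 0, 1, False))
    return info


def enumerate_walk_supports(graph, config: ExtractionConfig | None = None):
    """All distinct edge-multiplicity vectors of single alternating cycles
    and s->t trails, subject to the per-edge caps."""
    config = config or ExtractionConfig()
    info = _edge_info(graph, config)
    n = len(info)
    incident: dict = {}
    for i, (_, _, nds, _, _, _, _) in enumerate(info):
        for nd in set(nds):
            incident.setdefault(nd, []).append(i)

    supports: set[tuple] = set()

    def other(i, node):
        a, b = info[i][2]
        return b if node == a else a

    def dfs_cycle(start, node, cls, used, start_cls):
        for i in incident.get(node, ()):  # try every continuing edge
            if info[i][1] != ("seq" if cls == "seq" else "bp"):
                continue
            if used[i] >= info[i][5]:
                continue
            used[i] += 1
            nxt = other(i, node)
            ncls = "bp" if cls == "seq" else "seq"
            if nxt == start and ncls == start_cls:
                supports.add(tuple(used))
            if sum(used) < 12:  # depth bound: trails on <= 6 edges stay tiny
                dfs_cycle(start, nxt, ncls, used, start_cls)
            used[i] -= 1

    nodes = sorted(incident, key=lambda nd: (nd.chrom, nd.position, nd.side))
    genomic = [nd for nd in nodes if not nd.is_source]
    for start in genomic:
        for start_cls in ("seq", "bp"):
            dfs_cycle(start, start, start_cls, [0] * n, start_cls)

    s_node = next((nd for nd in nodes if nd.is_source and nd.chrom == "s"), None)
    if s_node is not None:

        def dfs_path(node, cls, used):
            if node.is_source and node.chrom == "t":
                supports.add(tuple(used))
                return
            for i in incident.get(node, ()):
                if info[i][1] != ("seq" if cls == "seq" else "bp"):
                    continue
                if used[i] >= info[i][5]:
                    continue
                if info[i][1] == "bp" and node.is_source and node.chrom == "t":
                    continue
                used[i] += 1
                if sum(used) < 14:
                    dfs_path(other(i, node), "bp" if cls == "seq" else "seq", used)
                used[i] -= 1

        dfs_path(s_node, "bp", [0] * n)

    keys = [rec[0] for rec in info]
    return [dict(zip(keys, sup)) for sup in sorted(supports)], info


def best_full_objective(
    graph,
    constraints,
    config: ExtractionConfig | None = None,
    max_walks: int = 3,
):
    """Exhaustive optimum of the full-mode objective, or None if no
    decomposition of <= max_walks walks meets (alpha, beta)."""
    config = config or ExtractionConfig()
    supports, info = enumerate_walk_supports(graph, config)
    cl = length_weighted_cn(graph)
    cn = {rec[0]: rec[3] for rec in info}
    seq_len = {rec[0]: rec[4] for rec in info if rec[1] == "seq"}
    m = len(constraints)
    w_max = max(rec[3] for rec in info)
    w_min = max(config.weight_floor_frac * w_max, 1e-9)
    best = None
    for r in range(0, max_walks + 1):
        for combo in combinations(range(len(supports)), r):
            chosen = [supports[i] for i in combo]
            if r:
                # LP: maximize total explained mass subject to edge capacity
                c = [-sum(sup.get(k, 0) * L for k, L in seq_len.items()) for sup in chosen]
                A, b = [], []
                for key, capacity in cn.items():
                    row = [sup.get(key, 0) for sup in chosen]
                    if any(row):
                        A.append(row)
                        b.append(capacity)
                res = linprog(
                    c,
                    A_ub=np.array(A),
                    b_ub=np.array(b),
                    bounds=[(w_min, None)] * r,
                    method="highs",
                )
                if not res.success:
                    continue
                mass = -res.fun
            else:
                mass = 0.0
            sat = sum(
                1
                for con in constraints
                if any(
                    all(sup.get(k, 0) >= cntr for k, cntr in con.edge_counts.items())
                    for sup in chosen
                )
            )
            if mass < config.alpha * cl - 1e-6 * max(cl, 1.0):
                continue
            if m and sat < config.beta * m - 1e-9:
                continue
            obj = r - (mass / cl if cl else 0.0) - (sat / m if m else 0.0)
            if best is None or obj < best - 1e-12:
                best = obj
    return best


def random_small_graph(rng, max_edges: int = 6):
    """A random balanced breakpoint graph with <= max_edges edges and small
    integer CN, built by superposing 1-2 random alternating cycles, plus an
    optional subwalk constraint taken from one of them."""
    from ecrecon.cycles import SubwalkConstraint, estimate_multiplicity_caps
    from ecrecon.model import (
        Breakend,
        BreakpointGraph,
        ConcordantEdge,
        DiscordantEdge,
        SequenceEdge,
    )

    while True:
        n_seg = int(rng.integers(2, 4))
        g = BreakpointGraph(amplicon_id=1)
        for i in range(1, n_seg + 1):
            g.add(SequenceEdge("chr1", i, i, cn=1.0))
        for i in range(1, n_seg):
            g.add(ConcordantEdge("chr1", i, cn=1.0))
        budget = max_edges - (2 * n_seg - 1)
        candidates = []
        for pa in range(1, n_seg + 1):
            for oa in "+-":
                for pb in range(1, n_seg + 1):
                    for ob in "+-":
                        a, b = Breakend("chr1", pa, oa), Breakend("chr1", pb, ob)
                        if (a, b) > (b, a):
                            continue
                        if a.chrom == b.chrom and oa == "+" and ob == "-" and b.position - a.position == 1:
                            continue
                        candidates.append((a, b))
        rng.shuffle(candidates)
        for a, b in candidates[: int(rng.integers(1, budget + 1))]:
            g.add(DiscordantEdge(a, b, cn=1.0, max_multiplicity=2))
        g.sort()

        from ecrecon.cycles import ExtractionConfig

        supports, info = enumerate_walk_supports(g, ExtractionConfig())
        if not supports:
            continue
        keys = [rec[0] for rec in info]
        chosen_idx = rng.choice(len(supports), size=int(rng.integers(1, 3)), replace=True)
        cn = dict.fromkeys(keys, 0.0)
        for i in set(int(j) for j in chosen_idx):
            w = float(rng.integers(1, 9))
            for k, x in supports[i].items():
                cn[k] += w * x
        for e in g.all_edges():
            e.cn = cn[e.key()]
        if length_weighted_cn(g) <= 0:
            continue
        estimate_multiplicity_caps(g)

        constraints = []
        if rng.random() < 0.7:
            sup = supports[int(rng.choice([int(j) for j in chosen_idx]))]
            chain = [k for k, x in sup.items() for _ in range(x)]
            if chain:
                constraints.append(SubwalkConstraint(0, chain, graph_id=1))
        return g, constraints


def decomposition_objective(decomp, graph) -> float:
    """Full-mode objective value of a returned decomposition."""
    cl = length_weighted_cn(graph)
    mass = sum(w.mass for w in decomp.walks)
    m = decomp.n_subwalks
    return len(decomp.walks) - mass / cl - (decomp.subwalks_satisfied / m if m else 0.0)
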