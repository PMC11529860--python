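"""Cycle/walk extraction from a balanced breakpoint graph.

The amplicon encoded by the graph is a superposition of *cycles* (closed
alternating sequences of sequence and breakpoint edges — candidate ecDNA)
and *s-t walks* (linear amplifications), each with a positive copy number.
We seek a minimum number of such walks that jointly explain a large
fraction of the graph's length-weighted copy number C_l(G) and satisfy a
large fraction of the *subwalk constraints* — ordered edge chains implied
by individual long reads spanning two or more junctions.

The optimization is a mixed-integer program with bilinear terms
w_i * x_uvi (walk copy number times integer edge multiplicity).  Both the
full mode (joint solve over at most k walks) and the greedy mode (repeated
single-walk extraction) are implemented as exact mixed-integer *linear*
programs: each bounded integer multiplicity is binary-expanded and each
bit-weight product is linearized exactly (McCormick on a binary factor),
then solved with the HiGHS backend of :func:`scipy.optimize.milp`.
Connectivity of each walk's support subgraph is enforced with a
single-commodity flow; together with per-node class balance (sequence vs
breakpoint incidences, foldbacks counting twice) this is necessary and
sufficient for the multiplicities to form a single alternating closed
trail or s-t trail, which is then reconstructed by a Hierholzer sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (
    Breakend,
    BreakpointGraph,
    ConcordantEdge,
    DiscordantEdge,
    SequenceEdge,
    SourceEdge,
    length_weighted_cn,
)

logger = logging.getLogger(__name__)

__all__ = [
    "INFEASIBLE",
    "SolverError",
    "SubwalkConstraint",
    "Walk",
    "ExtractionConfig",
    "Decomposition",
    "edge_caps",
    "estimate_multiplicity_caps",
    "extract_subwalk_constraints",
    "solve_miqcp_full",
    "solve_miqcp_greedy",
    "extract_cycles",
    "satisfies_subwalk",
    "heaviest_cycles",
]


class _Infeasible:
    def __repr__(self) -> str:  # pragma: no cover
        return "INFEASIBLE"


#: sentinel returned by :func:`solve_miqcp_full` when no k-walk solution
#: meets the (alpha, beta) requirements
INFEASIBLE = _Infeasible()


class SolverError(RuntimeError):
    """MILP backend failure (no solution and not provably infeasible)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SubwalkConstraint:
    """The edge chain traversed by one long read spanning >= 2 junctions.

    ``edge_chain`` is the ordered list of edge keys (alternating sequence and
    breakpoint edges); ``edge_counts`` the multiset view used for the weak
    (subgraph) satisfaction semantics.  A chain equals its reverse.
    """

    id: int
    edge_chain: list[tuple]
    support: int = 1
    graph_id: int | None = None
    satisfied: bool = False

    def __post_init__(self) -> None:
        self.edge_chain = list(self.edge_chain)
        counts: dict[tuple, int] = {}
        for k in self.edge_chain:
            counts[k] = counts.get(k, 0) + 1
        self.edge_counts = counts

    @staticmethod
    def canonical_chain(chain: list[tuple]) -> tuple:
        fwd, rev = tuple(chain), tuple(reversed(chain))
        return min(fwd, rev)


@dataclass
class Walk:
    """A cycle or s->t walk with its copy number and edge multiplicities."""

    node_sequence: list
    is_cycle: bool
    copy_number: float
    edge_multiplicity: dict[tuple, int]
    graph_id: int | None = None
    mass: float = 0.0  # w * sum over sequence edges of x * l
    #: keys of the edges traversed, in walk order (len(node_sequence) - 1)
    edge_sequence: list[tuple] = field(default_factory=list)

    @property
    def active(self) -> bool:
        return bool(self.edge_multiplicity) and self.copy_number > 0

    def first_coordinate(self) -> tuple:
        coords = [k[1:3] for k in self.edge_multiplicity if k[0] == "sequence"]
        return min(coords) if coords else ("", 0)

    def oriented_segments(self) -> list[tuple[str, int, int, str]]:
        """Sequence-edge traversals in walk order as (chrom, start, end, strand):
        forward when entered at the segment's start node, reverse otherwise."""
        segs = []
        for u, key in zip(self.node_sequence, self.edge_sequence):
            if key[0] != "sequence":
                continue
            _, chrom, start, end = key
            segs.append((chrom, start, end, "+" if u.position == start and u.side == "start" else "-"))
        return segs


@dataclass
class ExtractionConfig:
    """Knobs of the decomposition.

    ``alpha``/``beta`` are the minimum explained fractions of length-weighted
    copy number and of subwalk constraints; ``epsilon`` stops the greedy loop
    when the next walk's copy number falls below ``epsilon * C_l(G)``;
    ``gamma_coeff`` scales the greedy subwalk bonus
    (gamma = gamma_coeff * C_l(residual) / #unsatisfied).
    """

    alpha: float = 0.9
    beta: float = 0.9
    k_init: int = 10
    gamma_coeff: float = 0.01
    epsilon: float = 0.005
    full_mode_edge_cap: int = 100
    variable_cap: int = 10_000
    postprocess: bool = False
    concordant_multiplicity_cap: int = 4
    multiplicity_cap: int = 8  # hard per-edge per-walk ceiling
    weight_floor_frac: float = 1e-6
    time_limit: float = 300.0
    strict_ordered_subwalks: bool = False  # reserved: subgraph semantics used

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class Decomposition:
    """Result of cycle extraction."""

    walks: list[Walk]
    total_cl: float
    cn_fraction_explained: float
    subwalks_satisfied: int
    n_subwalks: int
    residual_cl: float
    solver_status: str
    mode: str
    k_used: int = 0
    backend: str = "scipy-highs-milp-linearized"

    def validate(self, graph: BreakpointGraph, tol: float = 1e-6) -> None:
        """No edge over-explanation: sum_i w_i * x_ei <= CN(e) + tol."""
        scale = max((e.cn for e in graph.all_edges()), default=1.0)
        for e in graph.all_edges():
            used = sum(
                w.copy_number * w.edge_multiplicity.get(e.key(), 0) for w in self.walks
            )
            if used > e.cn + tol * max(scale, 1.0) + 1e-9:
                raise AssertionError(
                    f"edge {e.key()} over-explained: {used:.6g} > CN {e.cn:.6g}"
                )


# ---------------------------------------------------------------------------
# Edge bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class _Edge:
    key: tuple
    kind: str  # sequence / concordant / discordant / source
    cls: str  # 'seq' or 'bp'
    nodes: tuple
    cn: float
    length: int
    cap: int
    is_foldback: bool = False
    source_side: str = ""


def estimate_multiplicity_caps(graph: BreakpointGraph, cap: int = 5) -> None:
    """Set R(u, v) on each discordant edge.

    With read support: proportional to the edge's support in units of the
    amplicon's median junction support (the typical support of a
    once-traversed junction), floored at 1 and capped.  Without read data:
    ceil(CN(e) / max discordant CN).
    """
    import statistics

    disc = graph.discordant_edges
    if not disc:
        return
    supports = [e.read_support for e in disc]
    if max(supports) > 0:
        unit = max(statistics.median(supports), 1.0)
        for e in disc:
            e.max_multiplicity = int(min(cap, max(1, round(e.read_support / unit))))
    else:
        mx_cn = max((e.cn for e in disc), default=0.0)
        for e in disc:
            if mx_cn <= 0 or e.cn <= 0:
                e.max_multiplicity = 1
            else:
                e.max_multiplicity = int(min(cap, max(1, math.ceil(e.cn / mx_cn))))


def edge_caps(graph: BreakpointGraph, config: ExtractionConfig) -> dict[tuple, int]:
    """Per-walk traversal caps for every edge.

    Discordant edges use their R(u, v); concordant edges a configured cap;
    source edges are traversable once (s is first, t is last); a sequence
    edge is capped by the breakpoint-incidence budget at its scarcer
    endpoint (each traversal consumes one breakpoint incidence per side).
    """
    caps: dict[tuple, int] = {}
    for e in graph.discordant_edges:
        caps[e.key()] = max(1, min(config.multiplicity_cap, e.max_multiplicity))
    for e in graph.concordant_edges:
        caps[e.key()] = min(config.multiplicity_cap, config.concordant_multiplicity_cap)
    for e in graph.source_edges:
        caps[e.key()] = 1
    for e in graph.sequence_edges:
        budget = []
        for node in e.nodes():
            b = 0
            for c in graph.concordant_edges:
                if node in c.nodes():
                    b += caps[c.key()]
            for d in graph.discordant_edges:
                if node in d.nodes():
                    b += caps[d.key()] * (2 if d.is_foldback else 1)
            for s in graph.source_edges:
                if node in s.nodes():
                    b += caps[s.key()]
            budget.append(b)
        caps[e.key()] = max(1, min(config.multiplicity_cap, min(budget)))
    return caps


def _edge_table(graph: BreakpointGraph, config: ExtractionConfig) -> list[_Edge]:
    graph.sort()
    caps = edge_caps(graph, config)
    table: list[_Edge] = []
    for e in graph.sequence_edges:
        table.append(
            _Edge(e.key(), "sequence", "seq", e.nodes(), e.cn, e.length, caps[e.key()])
        )
    for e in graph.concordant_edges:
        table.append(_Edge(e.key(), "concordant", "bp", e.nodes(), e.cn, 0, caps[e.key()]))
    for e in graph.discordant_edges:
        table.append(
            _Edge(
                e.key(),
                "discordant",
                "bp",
                e.nodes(),
                e.cn,
                0,
                caps[e.key()],
                is_foldback=e.is_foldback,
            )
        )
    for e in graph.source_edges:
        table.append(
            _Edge(e.key(), "source", "bp", e.nodes(), e.cn, 0, 1, source_side=e.source)
        )
    return table


def _nodes_of(table: list[_Edge]) -> list:
    seen: dict = {}
    for e in table:
        for n in e.nodes:
            seen.setdefault(n)
    return list(seen)


# ---------------------------------------------------------------------------
# MILP builder
# ---------------------------------------------------------------------------


class _Milp:
    def __init__(self) -> None:
        self.obj: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integ: list[int] = []
        self.rows: list[tuple[dict[int, float], float, float]] = []

    def var(self, lo: float, hi: float, integer: bool = False, obj: float = 0.0) -> int:
        self.obj.append(obj)
        self.lb.append(lo)
        self.ub.append(hi)
        self.integ.append(1 if integer else 0)
        return len(self.obj) - 1

    def con(self, coeffs: dict[int, float], lo: float, hi: float) -> None:
        self.rows.append((coeffs, lo, hi))

    def solve(self, time_limit: float):
        n = len(self.obj)
        data, ri, ci = [], [], []
        rlo, rhi = [], []
        for r, (coeffs, lo, hi) in enumerate(self.rows):
            for c, v in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
            rlo.append(lo)
            rhi.append(hi)
        A = sparse.csc_array((data, (ri, ci)), shape=(len(self.rows), n))
        res = milp(
            c=np.asarray(self.obj),
            constraints=LinearConstraint(A, np.asarray(rlo), np.asarray(rhi)),
            integrality=np.asarray(self.integ),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
            options={"time_limit": time_limit, "presolve": True},
        )
        return res


def _estimate_variables(n_edges: int, n_nodes: int, k: int, max_bits: int = 3) -> int:
    per_walk = n_edges * (2 + 2 * max_bits) + 2 * n_nodes + 2 * n_edges + 2
    return k * per_walk


def _build_walk_block(
    lp: _Milp,
    table: list[_Edge],
    nodes: list,
    cn_by_edge: dict[tuple, float],
    w_max: float,
    w_min: float,
):
    """Variables + structural constraints for one walk; returns handles."""
    V = len(nodes)
    has_source = any(e.kind == "source" for e in table)

    z = lp.var(0, 1, integer=True)
    w = lp.var(0, w_max)
    lp.con({w: 1.0, z: -w_max}, -np.inf, 0.0)  # w <= Cl(G) * z   (Eq. 4)
    lp.con({w: 1.0, z: -w_min}, 0.0, np.inf)  # w >= w_min * z

    x: list[int] = []
    u: list[int] = []
    bits: list[list[int]] = []
    prods: list[list[tuple[int, float]]] = []  # (q_var, 2^r) pairs per edge
    for e in table:
        xe = lp.var(0, e.cap, integer=True)
        ue = lp.var(0, 1, integer=True)
        lp.con({xe: 1.0, ue: -1.0}, 0.0, np.inf)  # x >= u
        lp.con({xe: 1.0, ue: -float(e.cap)}, -np.inf, 0.0)  # x <= cap * u
        lp.con({ue: 1.0, z: -1.0}, -np.inf, 0.0)  # u <= z
        nb = max(1, int(e.cap).bit_length())
        eb: list[int] = []
        ep: list[tuple[int, float]] = []
        link = {xe: -1.0}
        for r in range(nb):
            b = lp.var(0, 1, integer=True)
            link[b] = float(2**r)
            q = lp.var(0, w_max)
            lp.con({q: 1.0, b: -w_max}, -np.inf, 0.0)  # q <= Wmax b
            lp.con({q: 1.0, w: -1.0}, -np.inf, 0.0)  # q <= w
            lp.con({q: 1.0, w: -1.0, b: -w_max}, -w_max, np.inf)  # q >= w - Wmax(1-b)
            eb.append(b)
            ep.append((q, float(2**r)))
        lp.con(link, 0.0, 0.0)  # x = sum 2^r b
        x.append(xe)
        u.append(ue)
        bits.append(eb)
        prods.append(ep)

    # z active iff some edge used
    lp.con({z: 1.0, **{xe: -1.0 for xe in x}}, -np.inf, 0.0)

    node_index = {n: i for i, n in enumerate(nodes)}
    incident: dict[int, list[int]] = {i: [] for i in range(V)}
    for ei, e in enumerate(table):
        for n in set(e.nodes):
            incident[node_index[n]].append(ei)

    # s-t walk indicator and class balance
    y = None
    if has_source:
        y = lp.var(0, 1, integer=True)
        lp.con({y: 1.0, z: -1.0}, -np.inf, 0.0)
        for side in ("s", "t"):
            coeffs = {
                x[ei]: 1.0
                for ei, e in enumerate(table)
                if e.kind == "source" and e.source_side == side
            }
            if coeffs:
                coeffs[y] = -1.0
                lp.con(coeffs, 0.0, 0.0)
            else:
                lp.con({y: 1.0}, 0.0, 0.0)

    for n, vi in node_index.items():
        if getattr(n, "is_source", False):
            continue
        coeffs: dict[int, float] = {}
        for ei in incident[vi]:
            e = table[ei]
            if e.cls == "seq":
                coeffs[x[ei]] = coeffs.get(x[ei], 0.0) + 1.0
            else:
                mult = 2.0 if e.is_foldback else 1.0
                coeffs[x[ei]] = coeffs.get(x[ei], 0.0) - mult
        lp.con(coeffs, 0.0, 0.0)

    # connectivity: single-commodity flow from a chosen root over used edges
    nvar = [lp.var(0, 1, integer=True) for _ in range(V)]
    rvar = [lp.var(0, 1, integer=True) for _ in range(V)]
    lp.con({r: 1.0 for r in rvar} | {z: -1.0}, 0.0, 0.0)
    for vi in range(V):
        lp.con({rvar[vi]: 1.0, nvar[vi]: -1.0}, -np.inf, 0.0)
        lp.con({nvar[vi]: 1.0, **{u[ei]: -1.0 for ei in incident[vi]}}, -np.inf, 0.0)
    for vi in range(V):
        for ei in incident[vi]:
            lp.con({nvar[vi]: 1.0, u[ei]: -1.0}, 0.0, np.inf)
    flow_in: dict[int, list[int]] = {vi: [] for vi in range(V)}
    flow_out: dict[int, list[int]] = {vi: [] for vi in range(V)}
    for ei, e in enumerate(table):
        a, b = (node_index[e.nodes[0]], node_index[e.nodes[1]])
        if a == b:
            continue
        for src, dst in ((a, b), (b, a)):
            f = lp.var(0, float(V))
            lp.con({f: 1.0, u[ei]: -float(V)}, -np.inf, 0.0)
            flow_out[src].append(f)
            flow_in[dst].append(f)
    for vi in range(V):
        coeffs = {f: 1.0 for f in flow_in[vi]}
        for f in flow_out[vi]:
            coeffs[f] = coeffs.get(f, 0.0) - 1.0
        coeffs[nvar[vi]] = coeffs.get(nvar[vi], 0.0) - 1.0
        coeffs[rvar[vi]] = coeffs.get(rvar[vi], 0.0) + float(V)
        lp.con(coeffs, 0.0, np.inf)

    return {"z": z, "w": w, "y": y, "x": x, "u": u, "prods": prods}


def _add_subwalk_vars(
    lp: _Milp,
    table: list[_Edge],
    blocks: list[dict],
    constraints: list[SubwalkConstraint],
) -> list[int]:
    """P_j indicators with weak (subgraph) satisfaction semantics."""
    key_index = {e.key: i for i, e in enumerate(table)}
    pvars: list[int] = []
    for c in constraints:
        p = lp.var(0, 1, integer=True)
        pvars.append(p)
        if any(k not in key_index for k in c.edge_counts):
            lp.con({p: 1.0}, 0.0, 0.0)  # chain uses an edge absent from G
            continue
        if any(c.edge_counts[k] > table[key_index[k]].cap for k in c.edge_counts):
            lp.con({p: 1.0}, 0.0, 0.0)
            continue
        svars = []
        for blk in blocks:
            s = lp.var(0, 1, integer=True)
            for k, cnt in c.edge_counts.items():
                lp.con({blk["x"][key_index[k]]: 1.0, s: -float(cnt)}, 0.0, np.inf)
            svars.append(s)
        lp.con({p: 1.0, **{s: -1.0 for s in svars}}, -np.inf, 0.0)
    return pvars


# ---------------------------------------------------------------------------
# Trail reconstruction (Hierholzer for alternating trails)
# ---------------------------------------------------------------------------


def _flip(cls: str) -> str:
    return "bp" if cls == "seq" else "seq"


def _reconstruct_trail(table: list[_Edge], mult: dict[tuple, int], is_path: bool):
    """Turn per-edge multiplicities into an alternating node sequence.

    Hierholzer's algorithm adapted to alternating trails: build an initial
    circuit (or s->t trail), then repeatedly splice in sub-circuits at
    visited nodes with unused incidences.  Class balance guarantees the walk
    never gets stuck away from its start; the MILP's flow constraint
    guarantees splicing always finds an attachment point.
    """
    remaining = {e.key: mult.get(e.key, 0) for e in table}
    adj: dict = {}
    for e in table:
        if remaining[e.key] <= 0:
            continue
        a, b = e.nodes
        adj.setdefault(a, []).append(e)
        if b != a:
            adj.setdefault(b, []).append(e)

    def other_end(e: _Edge, node):
        a, b = e.nodes
        return b if node == a else a

    def take(node, cls):
        for e in adj.get(node, ()):  # deterministic: table order
            if e.cls == cls and remaining[e.key] > 0:
                remaining[e.key] -= 1
                return e
        return None

    def has_exit(node, cls):
        return any(e.cls == cls and remaining[e.key] > 0 for e in adj.get(node, ()))

    def replay(start, edges):
        pairs = []
        node = start
        for e in edges:
            pairs.append((node, e))
            node = other_end(e, node)
        return pairs, node

    def build_circuit(start, start_cls) -> list[_Edge]:
        edges: list[_Edge] = []
        node, cls = start, start_cls
        while True:
            e = take(node, cls)
            if e is None:
                raise SolverError(
                    f"stuck reconstructing trail at {node} needing {cls} "
                    "(solution is not a single alternating trail)"
                )
            edges.append(e)
            node = other_end(e, node)
            cls = _flip(cls)
            if node == start and cls == start_cls:
                return edges

    if is_path:
        start = next(n for n in adj if getattr(n, "is_source", False) and n.chrom == "s")
        edges: list[_Edge] = []
        node, cls = start, "bp"
        while True:
            e = take(node, cls)
            if e is None:
                break
            edges.append(e)
            node = other_end(e, node)
            cls = _flip(cls)
        if not (getattr(node, "is_source", False) and node.chrom == "t"):
            raise SolverError("s->t walk reconstruction did not end at t")
        pairs, end = replay(start, edges)
        # replaying consumes nothing; recompute end from the edges
        end = node
    else:
        start = min(adj, key=lambda n: (n.chrom, n.position, n.side))
        cls0 = "seq" if has_exit(start, "seq") else "bp"
        edges = build_circuit(start, cls0)
        pairs, end = replay(start, edges)

    while any(v > 0 for v in remaining.values()):
        spliced = False
        for pos, (v, out_e) in enumerate(pairs):
            if not (has_exit(v, "seq") or has_exit(v, "bp")):
                continue
            want = out_e.cls
            start_cls = want if has_exit(v, want) else _flip(want)
            sub_edges = build_circuit(v, start_cls)
            if sub_edges[0].cls != want:
                sub_edges = list(reversed(sub_edges))
            sub_pairs, _ = replay(v, sub_edges)
            pairs = pairs[:pos] + sub_pairs + pairs[pos:]
            spliced = True
            break
        if not spliced:
            raise SolverError("disconnected multiplicities: cannot splice sub-circuit")

    node_seq = [p[0] for p in pairs]
    node_seq.append(end)
    return [p[1] for p in pairs], node_seq


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def _extract_walks(
    table: list[_Edge], blocks: list[dict], xsol: np.ndarray, graph_id: int
) -> list[Walk]:
    walks: list[Walk] = []
    for blk in blocks:
        if round(xsol[blk["z"]]) < 1:
            continue
        mult = {
            table[ei].key: int(round(xsol[xe]))
            for ei, xe in enumerate(blk["x"])
            if round(xsol[xe]) >= 1
        }
        if not mult:
            continue
        w = float(xsol[blk["w"]])
        is_path = blk["y"] is not None and round(xsol[blk["y"]]) >= 1
        trail, nodes_seq = _reconstruct_trail(table, mult, is_path)
        mass = sum(
            w * mult.get(e.key, 0) * e.length for e in table if e.kind == "sequence"
        )
        walks.append(
            Walk(
                node_sequence=nodes_seq,
                is_cycle=not is_path,
                copy_number=w,
                edge_multiplicity=mult,
                graph_id=graph_id,
                mass=mass,
                edge_sequence=[e.key for e in trail],
            )
        )
    walks.sort(key=lambda wk: (-wk.mass, wk.first_coordinate()))
    return walks


def solve_miqcp_full(
    graph: BreakpointGraph,
    constraints: list[SubwalkConstraint],
    k: int,
    alpha: float = 0.9,
    beta: float = 0.9,
    config: ExtractionConfig | None = None,
):
    """Joint decomposition into at most *k* walks (Eq. 3-6 objective), or
    :data:`INFEASIBLE` when no k-walk solution meets (alpha, beta)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    config = config or ExtractionConfig(alpha=alpha, beta=beta)
    table = _edge_table(graph, config)
    nodes = _nodes_of(table)
    cl = length_weighted_cn(graph)
    if cl <= 0:
        return Decomposition([], 0.0, 1.0, len(constraints), len(constraints), 0.0, "trivial", "full")
    w_max = max(e.cn for e in table)  # no walk can exceed any used edge's CN
    w_min = max(config.weight_floor_frac * w_max, 1e-9)
    m = len(constraints)

    lp = _Milp()
    blocks = [_build_walk_block(lp, table, nodes, {}, w_max, w_min) for _ in range(k)]
    for b1, b2 in zip(blocks, blocks[1:]):  # symmetry breaking
        lp.con({b1["z"]: 1.0, b2["z"]: -1.0}, 0.0, np.inf)

    # capacity: sum_i w_i x_ei <= CN(e) on every edge
    for ei, e in enumerate(table):
        coeffs: dict[int, float] = {}
        for blk in blocks:
            for q, scale in blk["prods"][ei]:
                coeffs[q] = scale
        lp.con(coeffs, -np.inf, e.cn)

    # objective: min sum z - (1/Cl) * mass - (1/m) * sum P
    mass_coeffs: dict[int, float] = {}
    for ei, e in enumerate(table):
        if e.kind != "sequence":
            continue
        for blk in blocks:
            for q, scale in blk["prods"][ei]:
                mass_coeffs[q] = mass_coeffs.get(q, 0.0) + scale * e.length
    for blk in blocks:
        lp.obj[blk["z"]] += 1.0
    for q, coef in mass_coeffs.items():
        lp.obj[q] -= coef / cl

    pvars = _add_subwalk_vars(lp, table, blocks, constraints)
    for p in pvars:
        lp.obj[p] -= 1.0 / m if m else 0.0

    # Eq. 5: explained mass >= alpha * Cl(G)
    lp.con(dict(mass_coeffs), alpha * cl - 1e-9 * cl, np.inf)
    # Eq. 6: satisfied subwalks >= beta * m
    if m:
        lp.con({p: 1.0 for p in pvars}, beta * m - 1e-9, np.inf)

    res = lp.solve(config.time_limit)
    if res.status == 2:
        return INFEASIBLE
    if res.x is None:
        raise SolverError(f"MILP backend returned no solution: {res.message}")
    status = "optimal" if res.status == 0 else f"partial({res.message})"
    walks = _extract_walks(table, blocks, res.x, graph.amplicon_id)
    mass = sum(w.mass for w in walks)
    sat = _count_satisfied(walks, constraints)
    decomp = Decomposition(
        walks=walks,
        total_cl=cl,
        cn_fraction_explained=mass / cl,
        subwalks_satisfied=sat,
        n_subwalks=m,
        residual_cl=cl - mass,
        solver_status=status,
        mode="full",
        k_used=k,
    )
    decomp.validate(graph, tol=1e-5)
    return decomp


def _count_satisfied(walks: list[Walk], constraints: list[SubwalkConstraint]) -> int:
    count = 0
    for c in constraints:
        c.satisfied = any(satisfies_subwalk(w, c) for w in walks)
        count += c.satisfied
    return count


def _solve_single_walk(
    graph: BreakpointGraph,
    table: list[_Edge],
    residual: dict[tuple, float],
    constraints: list[SubwalkConstraint],
    unsatisfied: list[int],
    gamma: float,
    cl0: float,
    config: ExtractionConfig,
):
    nodes = _nodes_of(table)
    w_max = max((residual[e.key] for e in table), default=1.0)
    if w_max <= 0:
        return None
    w_min = max(config.weight_floor_frac * w_max, 1e-9)
    lp = _Milp()
    blk = _build_walk_block(lp, table, nodes, {}, w_max, w_min)
    lp.con({blk["z"]: 1.0}, 1.0, 1.0)
    for ei, e in enumerate(table):
        coeffs = {q: scale for q, scale in blk["prods"][ei]}
        lp.con(coeffs, -np.inf, max(residual[e.key], 0.0))
    for ei, e in enumerate(table):
        if e.kind != "sequence":
            continue
        for q, scale in blk["prods"][ei]:
            lp.obj[q] -= scale * e.length  # maximize mass
    sub = [constraints[j] for j in unsatisfied]
    pvars = _add_subwalk_vars(lp, table, [blk], sub)
    for p in pvars:
        lp.obj[p] -= gamma
    res = lp.solve(config.time_limit)
    if res.status == 2 or res.x is None:
        return None
    walks = _extract_walks(table, [blk], res.x, graph.amplicon_id)
    return walks[0] if walks else None


def solve_miqcp_greedy(
    graph: BreakpointGraph,
    constraints: list[SubwalkConstraint],
    config: ExtractionConfig | None = None,
) -> Decomposition:
    """Iterative extraction: repeatedly solve for the single walk maximizing
    explained mass plus a gamma-weighted bonus for newly satisfied subwalks
    (Eq. 7), removing each walk's copy number from the graph, until the
    (alpha, beta) targets are met or the next walk falls below
    epsilon * C_l(G)."""
    config = config or ExtractionConfig()
    table = _edge_table(graph, config)
    cl0 = length_weighted_cn(graph)
    m = len(constraints)
    residual = {e.key: e.cn for e in table}
    walks: list[Walk] = []
    satisfied: set[int] = set()
    explained = 0.0
    status = "optimal"
    max_rounds = 2 * len(table) + 10
    for _ in range(max_rounds):
        unsat = [j for j in range(m) if j not in satisfied]
        resid_cl = sum(
            residual[e.key] * e.length for e in table if e.kind == "sequence"
        )
        gamma = config.gamma_coeff * resid_cl / len(unsat) if unsat else 0.0
        walk = _solve_single_walk(
            graph, table, residual, constraints, unsat, gamma, cl0, config
        )
        if walk is None:
            status = "exhausted"
            break
        # stopping rule: the next walk's length-weighted CN falls below
        # epsilon * Cl(G)  (on unit-length segments this is its copy number)
        if walk.mass < config.epsilon * cl0:
            break
        walks.append(walk)
        explained += walk.mass
        for key, x in walk.edge_multiplicity.items():
            residual[key] = max(residual[key] - walk.copy_number * x, 0.0)
        for j in list(unsat):
            if satisfies_subwalk(walk, constraints[j]):
                satisfied.add(j)
        if explained >= config.alpha * cl0 and len(satisfied) >= config.beta * m:
            break
    for j, c in enumerate(constraints):
        c.satisfied = j in satisfied
    walks.sort(key=lambda wk: (-wk.mass, wk.first_coordinate()))
    decomp = Decomposition(
        walks=walks,
        total_cl=cl0,
        cn_fraction_explained=explained / cl0 if cl0 else 1.0,
        subwalks_satisfied=len(satisfied),
        n_subwalks=m,
        residual_cl=cl0 - explained,
        solver_status=status,
        mode="greedy",
    )
    decomp.validate(graph, tol=1e-5)
    return decomp


def extract_cycles(
    graph: BreakpointGraph,
    constraints: list[SubwalkConstraint],
    config: ExtractionConfig | None = None,
) -> Decomposition:
    """Mode-selection driver.

    Full mode for graphs with at most ``full_mode_edge_cap`` edges, doubling
    k from ``k_init`` on INFEASIBLE until k exceeds |E| or the estimated
    variable count trips ``variable_cap``; greedy otherwise, with an optional
    full-mode re-solve at the relaxed (alpha, beta) implied by the greedy
    residuals."""
    config = config or ExtractionConfig()
    n_edges = graph.num_edges
    n_nodes = len(graph.nodes)
    if n_edges <= config.full_mode_edge_cap:
        k = config.k_init
        while True:
            if _estimate_variables(n_edges, n_nodes, k) > config.variable_cap:
                logger.info("variable cap tripped at k=%d; switching to greedy", k)
                break
            result = solve_miqcp_full(
                graph, constraints, k, config.alpha, config.beta, config
            )
            if result is not INFEASIBLE:
                return result
            if k > n_edges:
                logger.info("full mode infeasible beyond k=|E|; switching to greedy")
                break
            k *= 2
    decomp = solve_miqcp_greedy(graph, constraints, config)
    if config.postprocess and decomp.walks:
        cl = decomp.total_cl
        alpha2 = min(0.9, 1.0 - decomp.residual_cl / cl) if cl else 0.0
        unsat = decomp.n_subwalks - decomp.subwalks_satisfied
        beta2 = min(0.9, 1.0 - unsat / decomp.n_subwalks) if decomp.n_subwalks else 0.0
        k = max(config.k_init, len(decomp.walks))
        while _estimate_variables(n_edges, n_nodes, k) <= config.variable_cap:
            result = solve_miqcp_full(graph, constraints, k, alpha2, beta2, config)
            if result is not INFEASIBLE:
                result.mode = "greedy+postprocess"
                return result
            if k > n_edges:
                break
            k *= 2
    return decomp


# ---------------------------------------------------------------------------
# Subwalk constraints from alignments
# ---------------------------------------------------------------------------


def extract_subwalk_constraints(
    alignments, graph: BreakpointGraph, window: int = 100, min_seq_overlap: int = 50
) -> list[SubwalkConstraint]:
    """Map each chimeric read whose chain crosses >= 2 graph junctions (at
    least one discordant) to a subwalk constraint; identical chains (a chain
    equals its reverse) are deduplicated with support incremented."""
    from .io import chain_junctions
    from .intervals import is_concordant_pair

    disc = list(graph.discordant_edges)
    conc_by_chrom: dict[str, list] = {}
    for c in graph.concordant_edges:
        conc_by_chrom.setdefault(c.chrom, []).append(c)
    seq_edges = sorted(graph.sequence_edges, key=lambda e: (e.chrom, e.start))

    def match_discordant(a: Breakend, b: Breakend):
        for e in disc:
            for p, q in ((e.breakend_a, e.breakend_b), (e.breakend_b, e.breakend_a)):
                if (
                    p.chrom == a.chrom
                    and q.chrom == b.chrom
                    and p.orientation == a.orientation
                    and q.orientation == b.orientation
                    and abs(p.position - a.position) <= window
                    and abs(q.position - b.position) <= window
                ):
                    return e
        return None

    def fragment_edges(frag) -> list[tuple]:
        keys = []
        for e in seq_edges:
            if e.chrom != frag.chrom:
                continue
            ov = min(frag.ref_end, e.end) - max(frag.ref_start, e.start) + 1
            if ov >= min(min_seq_overlap, e.length):
                keys.append(e.key())
        chain: list[tuple] = []
        for i, k in enumerate(keys):
            if i:
                prev_end = keys[i - 1][3]
                for c in conc_by_chrom.get(frag.chrom, ()):
                    if c.left_position == prev_end:
                        chain.append(c.key())
                        break
            chain.append(k)
        if frag.strand == "-":
            chain.reverse()
        return chain

    chains_seen: dict[tuple, SubwalkConstraint] = {}
    regions = [(e.chrom, e.start, e.end) for e in seq_edges]
    done_reads: set[str] = set()
    for chrom, start, end in regions:
        for chain in alignments.chimeric_chains(chrom, start, end):
            qname = chain[0].qname
            if qname in done_reads:
                continue
            done_reads.add(qname)
            junctions = chain_junctions(chain)
            edge_chain: list[tuple] = []
            n_disc = 0
            ok = True
            for idx, frag in enumerate(chain):
                edge_chain.extend(fragment_edges(frag))
                if idx < len(junctions):
                    a, b = junctions[idx]
                    if is_concordant_pair(a, b):
                        continue
                    e = match_discordant(a, b)
                    if e is None:
                        ok = False
                        break
                    edge_chain.append(e.key())
                    n_disc += 1
            if not ok or n_disc < 1:
                continue
            n_junc = sum(1 for k in edge_chain if k[0] in ("concordant", "discordant"))
            if n_junc < 2:
                continue
            canon = SubwalkConstraint.canonical_chain(edge_chain)
            if canon in chains_seen:
                chains_seen[canon].support += 1
            else:
                chains_seen[canon] = SubwalkConstraint(
                    id=len(chains_seen), edge_chain=list(canon), graph_id=graph.amplicon_id
                )
    out = list(chains_seen.values())
    for i, c in enumerate(out):
        c.id = i
    return out


# ---------------------------------------------------------------------------
# Satisfaction and ranking
# ---------------------------------------------------------------------------


def satisfies_subwalk(walk: Walk, constraint: SubwalkConstraint) -> bool:
    """Weak (subgraph) semantics: every edge of the constraint chain appears
    in the walk with multiplicity >= its multiplicity in the chain."""
    if (
        walk.graph_id is not None
        and constraint.graph_id is not None
        and walk.graph_id != constraint.graph_id
    ):
        raise ValueError("walk and constraint reference different graphs")
    if not walk.edge_multiplicity:
        return False
    return all(
        walk.edge_multiplicity.get(k, 0) >= cnt for k, cnt in constraint.edge_counts.items()
    )


def heaviest_cycles(decomposition: Decomposition, k: int):
    """Top-k walks by length-weighted copy number w_i * sum(x * l) and the
    cumulative fraction of C_l(G) they explain."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not decomposition.walks:
        raise ValueError("empty decomposition")
    ranked = sorted(decomposition.walks, key=lambda w: (-w.mass, w.first_coordinate()))
    top = ranked[:k]
    frac = sum(w.mass for w in top) / decomposition.total_cl if decomposition.total_cl else 0.0
    return top, frac
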