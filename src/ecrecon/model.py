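"""Breakpoint-graph data model for focal amplifications.

A breakpoint graph encodes a set of non-overlapping amplified reference
intervals together with the rearrangement junctions observed between them.

* *Sequence edges* are reference segments (1-based inclusive coordinates),
  each carrying a copy number (CN) and the total number of aligned
  nucleotides observed on it.
* *Concordant edges* join the end of one segment to the start of the next
  segment when the two are adjacent on the reference (positions differing
  by exactly 1, same orientation).
* *Discordant edges* are junctions between non-adjacent or re-oriented
  loci, evidenced by chimeric (split) long-read alignments.  A junction
  whose two breakends coincide with inverted orientation is a *foldback*
  (the signature of an inverted duplication).
* The special *source* nodes ``s`` and ``t`` attach via source edges
  (discordant-class) at amplicon boundaries and absorb copy-number flow
  entering or leaving the amplified region.

Copy numbers are *balanced* when, at each endpoint of every sequence edge,
the summed CN of incident breakpoint-class edges (concordant + discordant +
source, foldbacks counting twice) equals the sequence edge's CN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

__all__ = [
    "Side",
    "Breakend",
    "GraphNode",
    "SequenceEdge",
    "ConcordantEdge",
    "DiscordantEdge",
    "SourceEdge",
    "BreakpointGraph",
    "EmptyGraphError",
    "length_weighted_cn",
    "check_balance",
    "incident_edges",
]

#: default tolerance for copy-number balance checks after the MLE fit
DEFAULT_BALANCE_TOL = 1e-4


class EmptyGraphError(ValueError):
    """Raised when an operation requires a graph with sequence edges."""


class Side(str, Enum):
    """Which endpoint of a sequence edge a node represents."""

    START = "start"
    END = "end"


class Breakend(NamedTuple):
    """One side of a junction: ``(chrom, position, orientation)``.

    Orientation ``'+'`` means the junction leaves the segment at its higher
    coordinate (reading reference-forward into the break); ``'-'`` means it
    leaves at the lower coordinate.
    """

    chrom: str
    position: int
    orientation: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.position}{self.orientation}"


class GraphNode(NamedTuple):
    """A segment endpoint (or the source/sink ``s``/``t``)."""

    chrom: str
    position: int
    side: str  # Side value; "" for source nodes
    is_source: bool = False

    @classmethod
    def source(cls, name: str) -> "GraphNode":
        return cls(name, -1, "", True)


SOURCE_S = GraphNode.source("s")
SOURCE_T = GraphNode.source("t")


@dataclass
class SequenceEdge:
    """A reference segment [start, end] (1-based inclusive) with a CN."""

    chrom: str
    start: int
    end: int
    cn: float = 0.0
    observed_nucleotides: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"sequence edge start {self.start} > end {self.end}")
        if self.cn < 0:
            raise ValueError("sequence edge CN must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start_node(self) -> GraphNode:
        return GraphNode(self.chrom, self.start, Side.START.value)

    @property
    def end_node(self) -> GraphNode:
        return GraphNode(self.chrom, self.end, Side.END.value)

    def nodes(self) -> tuple[GraphNode, GraphNode]:
        return (self.start_node, self.end_node)

    def key(self) -> tuple:
        return ("sequence", self.chrom, self.start, self.end)


@dataclass
class ConcordantEdge:
    """Reference adjacency between the end of one segment and the start of
    the next (right position = left position + 1)."""

    chrom: str
    left_position: int
    cn: float = 0.0
    read_support: int = 0

    @property
    def left_node(self) -> GraphNode:
        return GraphNode(self.chrom, self.left_position, Side.END.value)

    @property
    def right_node(self) -> GraphNode:
        return GraphNode(self.chrom, self.left_position + 1, Side.START.value)

    def nodes(self) -> tuple[GraphNode, GraphNode]:
        return (self.left_node, self.right_node)

    def key(self) -> tuple:
        return ("concordant", self.chrom, self.left_position)


def _node_for_breakend(b: Breakend) -> GraphNode:
    # '+' breakends sit at the end-side of the segment they leave,
    # '-' breakends at the start-side.
    side = Side.END.value if b.orientation == "+" else Side.START.value
    return GraphNode(b.chrom, b.position, side)


@dataclass
class DiscordantEdge:
    """A rearrangement junction between two breakends.

    ``is_foldback`` marks self-junctions with both breakends at (nearly) the
    same locus with identical orientation, i.e. inverted duplications.
    """

    breakend_a: Breakend
    breakend_b: Breakend
    cn: float = 0.0
    read_support: int = 0
    max_multiplicity: int = 1  # per-walk traversal cap R(u, v)
    is_source_edge: bool = False

    def __post_init__(self) -> None:
        a, b = self.breakend_a, self.breakend_b
        if (
            a.chrom == b.chrom
            and a.orientation == "+"
            and b.orientation == "-"
            and b.position - a.position == 1
        ):
            raise ValueError(
                f"junction {a}->{b} is reference-adjacent (concordant, not discordant)"
            )

    @property
    def is_foldback(self) -> bool:
        a, b = self.breakend_a, self.breakend_b
        return a.chrom == b.chrom and a.orientation == b.orientation and a.position == b.position

    def nodes(self) -> tuple[GraphNode, GraphNode]:
        return (_node_for_breakend(self.breakend_a), _node_for_breakend(self.breakend_b))

    def key(self) -> tuple:
        a, b = sorted([self.breakend_a, self.breakend_b])
        return ("discordant", a, b)


@dataclass
class SourceEdge:
    """Edge joining a source node (``s``/``t``) to a genomic boundary node.

    Source edges belong to the discordant class for balance purposes: they
    absorb copy-number flow that enters or leaves the amplicon.
    """

    source: str  # "s" or "t"
    breakend: Breakend
    cn: float = 0.0

    def nodes(self) -> tuple[GraphNode, GraphNode]:
        src = SOURCE_S if self.source == "s" else SOURCE_T
        return (src, _node_for_breakend(self.breakend))

    def key(self) -> tuple:
        return ("source", self.source, self.breakend)


@dataclass
class BreakpointGraph:
    """A per-amplicon breakpoint graph (G = (V, Es u Ec u Ed, CN))."""

    amplicon_id: int = 0
    sequence_edges: list[SequenceEdge] = field(default_factory=list)
    concordant_edges: list[ConcordantEdge] = field(default_factory=list)
    discordant_edges: list[DiscordantEdge] = field(default_factory=list)
    source_edges: list[SourceEdge] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add(self, edge) -> None:
        if isinstance(edge, SequenceEdge):
            self.sequence_edges.append(edge)
        elif isinstance(edge, ConcordantEdge):
            self.concordant_edges.append(edge)
        elif isinstance(edge, DiscordantEdge):
            self.discordant_edges.append(edge)
        elif isinstance(edge, SourceEdge):
            self.source_edges.append(edge)
        else:  # pragma: no cover - defensive
            raise TypeError(type(edge))

    def sort(self) -> None:
        """Canonical deterministic edge ordering (chrom, position)."""
        self.sequence_edges.sort(key=lambda e: (e.chrom, e.start, e.end))
        self.concordant_edges.sort(key=lambda e: (e.chrom, e.left_position))
        self.discordant_edges.sort(key=lambda e: e.key())
        self.source_edges.sort(key=lambda e: e.key())

    # -- views -----------------------------------------------------------------

    @property
    def nodes(self) -> list[GraphNode]:
        seen: dict[GraphNode, None] = {}
        for e in self.sequence_edges:
            for n in e.nodes():
                seen.setdefault(n)
        if self.source_edges:
            seen.setdefault(SOURCE_S)
            seen.setdefault(SOURCE_T)
        return list(seen)

    def breakpoint_edges(self) -> list:
        """All breakpoint-class edges (concordant + discordant + source)."""
        return [*self.concordant_edges, *self.discordant_edges, *self.source_edges]

    def all_edges(self) -> list:
        return [*self.sequence_edges, *self.breakpoint_edges()]

    @property
    def num_edges(self) -> int:
        return len(self.all_edges())

    def sequence_edge_at(self, node: GraphNode):
        for e in self.sequence_edges:
            if node in e.nodes():
                return e
        return None

    def validate(self) -> None:
        """Structural invariants: unique edges, breakends on known nodes."""
        keys = [e.key() for e in self.all_edges()]
        if len(keys) != len(set(keys)):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate edges in graph: {dups}")
        node_set = set(self.nodes)
        for e in self.breakpoint_edges():
            for n in e.nodes():
                if not n.is_source and n not in node_set:
                    raise ValueError(f"edge {e.key()} references unknown node {n}")
        for e in self.sequence_edges:
            n_seq = sum(1 for other in self.sequence_edges if set(other.nodes()) & set(e.nodes()))
            if n_seq != 1:
                raise ValueError(f"node of {e.key()} incident to {n_seq} sequence edges")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def length_weighted_cn(graph: BreakpointGraph) -> float:
    """Total length-weighted copy number ``C_l(G) = sum CN(u,v) * l(u,v)``
    over sequence edges."""
    if not graph.sequence_edges:
        raise EmptyGraphError("graph has no sequence edges")
    return float(sum(e.cn * e.length for e in graph.sequence_edges))


def incident_edges(graph: BreakpointGraph, node: GraphNode) -> dict[str, list]:
    """Partition the edges incident on *node* into sequence / concordant /
    discordant (source edges count as discordant-class).

    Each edge is listed once; a foldback self-junction appears once here but
    contributes twice to the balance sum at its node.
    """
    if node not in set(graph.nodes):
        raise KeyError(f"node {node} not in graph")
    out: dict[str, list] = {"sequence": [], "concordant": [], "discordant": []}
    if node.is_source:
        name = "s" if node == SOURCE_S else "t"
        out["discordant"] = [e for e in graph.source_edges if e.source == name]
        return out
    for e in graph.sequence_edges:
        if node in e.nodes():
            out["sequence"].append(e)
    for e in graph.concordant_edges:
        if node in e.nodes():
            out["concordant"].append(e)
    for e in graph.discordant_edges:
        if node in e.nodes():
            out["discordant"].append(e)
    for e in graph.source_edges:
        if node in e.nodes():
            out["discordant"].append(e)
    return out


def balance_residual(graph: BreakpointGraph, node: GraphNode) -> float:
    """Breakpoint-class CN minus sequence-edge CN at *node* (foldback 2x)."""
    inc = incident_edges(graph, node)
    seq_cn = sum(e.cn for e in inc["sequence"])
    bp_cn = 0.0
    for e in inc["concordant"]:
        bp_cn += e.cn
    for e in inc["discordant"]:
        mult = 2.0 if isinstance(e, DiscordantEdge) and e.is_foldback else 1.0
        bp_cn += mult * e.cn
    return bp_cn - seq_cn


def check_balance(
    graph: BreakpointGraph, tolerance: float = DEFAULT_BALANCE_TOL
) -> list[tuple[GraphNode, float]]:
    """Return ``(node, residual)`` pairs at which the copy-number balance is
    violated beyond *tolerance* (empty list = balanced graph)."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    violations: list[tuple[GraphNode, float]] = []
    for node in graph.nodes:
        if node.is_source:
            continue
        r = balance_residual(graph, node)
        if abs(r) > tolerance:
            violations.append((node, r))
    return violations
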