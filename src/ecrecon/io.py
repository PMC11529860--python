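"""File formats: breakpoint-graph and cycles dialects, CNV tables, alignments.

The graph and cycles serializations follow the tab-separated dialect used by
the short-read amplicon-reconstruction ecosystem (``*_graph.txt`` /
``*_cycles.txt``), so downstream classifiers can consume the outputs.
Alignment ingestion is built on :mod:`pysam`; chimeric (split) alignments are
reconstructed into per-read chains from primary records plus their ``SA``
tags, ordered along the read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .model import (
    Breakend,
    BreakpointGraph,
    ConcordantEdge,
    DiscordantEdge,
    SequenceEdge,
    SourceEdge,
)

__all__ = [
    "write_graph",
    "read_graph",
    "CycleRecord",
    "write_cycles",
    "read_cycles",
    "read_cnv_calls",
    "read_seed_bed",
    "ReadFragment",
    "AlignmentSource",
    "chain_junctions",
]

_CN_FMT = "{:.6f}"


# ---------------------------------------------------------------------------
# Breakpoint-graph dialect
# ---------------------------------------------------------------------------


def _bnd_str(b: Breakend) -> str:
    return f"{b.chrom}:{b.position}{b.orientation}"


_BND_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)(?P<orient>[+-])$")


def _parse_bnd(s: str) -> Breakend:
    m = _BND_RE.match(s)
    if not m:
        raise ValueError(f"malformed breakend {s!r}")
    return Breakend(m["chrom"], int(m["pos"]), m["orient"])


def write_graph(graph: BreakpointGraph, path) -> None:
    """Serialize *graph* deterministically (edges sorted by chrom, position)."""
    graph.sort()
    lines = []
    for e in graph.sequence_edges:
        lines.append(
            "\t".join(
                [
                    "sequence",
                    f"{e.chrom}:{e.start}-",
                    f"{e.chrom}:{e.end}+",
                    _CN_FMT.format(e.cn),
                    str(int(round(e.observed_nucleotides))),
                    str(e.length),
                ]
            )
        )
    for e in graph.concordant_edges:
        left = Breakend(e.chrom, e.left_position, "+")
        right = Breakend(e.chrom, e.left_position + 1, "-")
        lines.append(
            "\t".join(
                [
                    "concordant",
                    f"{_bnd_str(left)}->{_bnd_str(right)}",
                    _CN_FMT.format(e.cn),
                    str(e.read_support),
                ]
            )
        )
    for e in graph.discordant_edges:
        lines.append(
            "\t".join(
                [
                    "discordant",
                    f"{_bnd_str(e.breakend_a)}->{_bnd_str(e.breakend_b)}",
                    _CN_FMT.format(e.cn),
                    str(e.read_support),
                    f"R={e.max_multiplicity}",
                ]
            )
        )
    for e in graph.source_edges:
        lines.append(
            "\t".join(
                ["source", f"{e.source}->{_bnd_str(e.breakend)}", _CN_FMT.format(e.cn)]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graph(path, amplicon_id: int = 0) -> BreakpointGraph:
    graph = BreakpointGraph(amplicon_id=amplicon_id)
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "sequence":
                chrom_s, start = fields[1][:-1].split(":")
                chrom_e, end = fields[2][:-1].split(":")
                graph.add(
                    SequenceEdge(
                        chrom_s,
                        int(start),
                        int(end),
                        cn=float(fields[3]),
                        observed_nucleotides=float(fields[4]),
                    )
                )
            elif kind == "concordant":
                left, _right = fields[1].split("->")
                b = _parse_bnd(left)
                graph.add(
                    ConcordantEdge(
                        b.chrom, b.position, cn=float(fields[2]), read_support=int(fields[3])
                    )
                )
            elif kind == "discordant":
                a_s, b_s = fields[1].split("->")
                rmax = 1
                if len(fields) > 4 and fields[4].startswith("R="):
                    rmax = int(fields[4][2:])
                graph.add(
                    DiscordantEdge(
                        _parse_bnd(a_s),
                        _parse_bnd(b_s),
                        cn=float(fields[2]),
                        read_support=int(fields[3]),
                        max_multiplicity=rmax,
                    )
                )
            elif kind == "source":
                src, bnd = fields[1].split("->")
                graph.add(SourceEdge(src, _parse_bnd(bnd), cn=float(fields[2])))
            else:
                raise ValueError(f"unknown graph record type {kind!r}")
    graph.sort()
    return graph


# ---------------------------------------------------------------------------
# Cycles dialect
# ---------------------------------------------------------------------------


@dataclass
class CycleRecord:
    """One extracted cycle or s->t walk as oriented reference segments."""

    index: int
    copy_number: float
    is_cycle: bool
    #: oriented segments: (chrom, start, end, orientation)
    segments: list[tuple[str, int, int, str]]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for _, s, e, _ in self.segments)


def write_cycles(records: Iterable[CycleRecord], path) -> None:
    records = list(records)
    seg_ids: dict[tuple[str, int, int], int] = {}
    for rec in records:
        for chrom, start, end, _ in rec.segments:
            seg_ids.setdefault((chrom, start, end), 0)
    for i, key in enumerate(sorted(seg_ids), start=1):
        seg_ids[key] = i
    lines = [
        f"Segment\t{i}\t{chrom}\t{start}\t{end}"
        for (chrom, start, end), i in sorted(seg_ids.items(), key=lambda kv: kv[1])
    ]
    for rec in records:
        toks = [f"{seg_ids[(c, s, e)]}{o}" for c, s, e, o in rec.segments]
        if not rec.is_cycle:
            toks = ["0+", *toks, "0-"]
        lines.append(
            f"Cycle={rec.index};Copy_count={_CN_FMT.format(rec.copy_number)};"
            f"Segments={','.join(toks)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cycles(path) -> list[CycleRecord]:
    segments: dict[int, tuple[str, int, int]] = {}
    records: list[CycleRecord] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Segment"):
                _, idx, chrom, start, end = line.split("\t")
                segments[int(idx)] = (chrom, int(start), int(end))
            elif line.startswith("Cycle="):
                kv = dict(part.split("=", 1) for part in line.split(";"))
                toks = kv["Segments"].split(",")
                is_cycle = not (toks[0] == "0+" and toks[-1] == "0-")
                if not is_cycle:
                    toks = toks[1:-1]
                segs = []
                for tok in toks:
                    sid, orient = int(tok[:-1]), tok[-1]
                    chrom, start, end = segments[sid]
                    segs.append((chrom, start, end, orient))
                records.append(
                    CycleRecord(
                        index=int(kv["Cycle"]),
                        copy_number=float(kv["Copy_count"]),
                        is_cycle=is_cycle,
                        segments=segs,
                    )
                )
            else:
                raise ValueError(f"unrecognized cycles line: {line!r}")
    return records


# ---------------------------------------------------------------------------
# CNV segment tables
# ---------------------------------------------------------------------------


def read_cnv_calls(path):
    """Read a tab-separated CNV segment table into :class:`CNVSegment` rows.

    Accepts CNVkit-style ``.cns`` column naming (chromosome, start, end, cn
    [, depth]); 0-based half-open starts are converted to 1-based inclusive.
    Segments must be sorted and non-overlapping per chromosome.
    """
    from .intervals import CNVSegment

    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    chrom_col = "chromosome" if "chromosome" in df.columns else "chrom"
    if chrom_col not in df.columns or "cn" not in df.columns:
        raise ValueError("CNV table must have chromosome/chrom, start, end, cn columns")
    depth = df["depth"] if "depth" in df.columns else pd.Series([float("nan")] * len(df))
    segments = [
        CNVSegment(
            chrom=str(row[chrom_col]),
            start=int(row["start"]) + 1,  # 0-based half-open -> 1-based inclusive
            end=int(row["end"]),
            cn=float(row["cn"]),
            mean_coverage=float(d),
        )
        for (_, row), d in zip(df.iterrows(), depth)
    ]
    _validate_segments(segments)
    return segments


def _validate_segments(segments) -> None:
    by_chrom: dict[str, list] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"CNV segments unsorted or overlapping on {chrom}: "
                    f"{a.start}-{a.end} then {b.start}-{b.end}"
                )


def read_seed_bed(path) -> list[tuple[str, int, int]]:
    """3-column BED seed intervals, converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadFragment:
    """One aligned piece of a (possibly chimeric) long read.

    Coordinates are 1-based inclusive on the reference; ``query_start`` /
    ``query_end`` are 0-based half-open offsets in the *original* read
    orientation, used to order fragments along the read.
    """

    qname: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    query_start: int
    query_end: int


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _fragment_from_cigar(qname, chrom, pos1, strand, cigar: str) -> ReadFragment:
    left_clip = right_clip = 0
    qlen = rlen = 0
    ops = _CIG_RE.findall(cigar)
    for i, (n_s, op) in enumerate(ops):
        n = int(n_s)
        if op in "SH":
            if qlen == 0 and i == 0:
                left_clip = n
            else:
                right_clip = n
        elif op in "M=X":
            qlen += n
            rlen += n
        elif op == "I":
            qlen += n
        elif op in "DN":
            rlen += n
    if strand == "+":
        qs = left_clip
    else:
        qs = right_clip
    return ReadFragment(qname, chrom, pos1, pos1 + rlen - 1, strand, qs, qs + qlen)


def _fragment_from_record(rec: pysam.AlignedSegment) -> ReadFragment:
    strand = "-" if rec.is_reverse else "+"
    return _fragment_from_cigar(
        rec.query_name, rec.reference_name, rec.reference_start + 1, strand, rec.cigarstring
    )


def _fragments_from_sa(qname: str, sa_tag: str) -> list[ReadFragment]:
    frags = []
    for entry in sa_tag.rstrip(";").split(";"):
        if not entry:
            continue
        rname, pos, strand, cigar, _mapq, _nm = entry.split(",")
        frags.append(_fragment_from_cigar(qname, rname, int(pos), strand, cigar))
    return frags


class AlignmentSource:
    """Indexed alignment file with chimeric-chain iteration.

    Requires a coordinate-sorted, indexed BAM/CRAM (or SAM with an index).
    """

    def __init__(self, path):
        self.path = str(path)
        self._af = pysam.AlignmentFile(self.path)
        if not self._af.has_index():
            raise OSError(
                f"{self.path} has no index; sort and index it (samtools index) first"
            )
        if self._af.mapped == 0:
            raise OSError(f"{self.path} contains no mapped reads")

    def close(self) -> None:
        self._af.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @property
    def references(self) -> dict[str, int]:
        return dict(zip(self._af.references, self._af.lengths))

    def fetch_fragments(self, chrom: str, start: int, end: int) -> Iterator[ReadFragment]:
        """All aligned fragments overlapping [start, end] (1-based inclusive)."""
        for rec in self._af.fetch(chrom, start - 1, end):
            if rec.is_unmapped or rec.is_secondary:
                continue
            yield _fragment_from_record(rec)

    def chimeric_chains(self, chrom: str, start: int, end: int) -> list[list[ReadFragment]]:
        """Per-read split-alignment chains for reads with a fragment in the
        region, ordered along the read (>= 2 fragments each).

        The full chain is reconstructed from any one record via its ``SA``
        tag, so fragments mapping outside the queried region are included.
        """
        chains: dict[str, list[ReadFragment]] = {}
        for rec in self._af.fetch(chrom, start - 1, end):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if not rec.has_tag("SA") or rec.query_name in chains:
                continue
            frags = [_fragment_from_record(rec)]
            frags.extend(_fragments_from_sa(rec.query_name, rec.get_tag("SA")))
            frags.sort(key=lambda f: (f.query_start, f.query_end))
            chains[rec.query_name] = frags
        return list(chains.values())


def chain_junctions(chain: list[ReadFragment]) -> list[tuple[Breakend, Breakend]]:
    """Breakend pairs at each split junction of a chain, in read order.

    The fragment left of the junction contributes its trailing breakend
    (reference end with ``'+'`` on the forward strand, reference start with
    ``'-'`` on the reverse strand); the right fragment contributes its
    leading breakend (mirror rule).
    """
    pairs = []
    for left, right in zip(chain, chain[1:]):
        if left.strand == "+":
            a = Breakend(left.chrom, left.ref_end, "+")
        else:
            a = Breakend(left.chrom, left.ref_start, "-")
        if right.strand == "+":
            b = Breakend(right.chrom, right.ref_start, "-")
        else:
            b = Breakend(right.chrom, right.ref_end, "+")
        pairs.append((a, b))
    return pairs
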