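"""Synthetic ground-truth amplicons and alignment-level long-read simulation.

Circular amplicon structures are generated by three formation mechanisms:

* **episomal** — a contiguous region is excised and circularized;
* **chromothripsis** — a region is shattered into fragments, a random subset
  is retained, shuffled and re-oriented, then circularized;
* **2-foldback** — the region is duplicated head-to-head, giving a circle
  with two foldback (inverted self-) junctions.

Each structure is then edited with internal structural variants (deletions,
duplications, inversions, insertions) until a target junction count is
reached, and its exact breakpoint graph (balanced by construction, on top
of a diploid CN-2 background) is emitted as ground truth.

Reads are simulated at the *alignment* level: mapped records with correct
clip sides, strands and ``SA`` tags are drawn directly along the circular
amplicon sequence (at the amplicon coverage) and along the linear reference
(at the diploid background coverage), so the pipeline's exact inputs are
exercised without an external aligner.  Mapping noise reduces to a
configurable breakend jitter and a junction false-negative rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .intervals import CNVSegment
from .io import CycleRecord, write_cycles, write_graph
from .model import (
    Breakend,
    BreakpointGraph,
    ConcordantEdge,
    DiscordantEdge,
    SequenceEdge,
    SourceEdge,
)

__all__ = [
    "SyntheticReference",
    "ReadSimConfig",
    "SimulatedAmplicon",
    "simulate_structure",
    "simulate_alignments",
    "make_test_dataset",
    "truth_cnv_segments",
    "write_cnv_table",
]

MECHANISMS = ("episomal", "chromothripsis", "2-foldback")

#: oriented reference segment: (chrom, start, end, strand)
Segment = tuple[str, int, int, str]


@dataclass(frozen=True)
class SyntheticReference:
    """A set of chromosome lengths (no base-level sequence is needed for
    alignment-level simulation; a deterministic sequence is available for
    completeness)."""

    lengths: dict[str, int]

    @classmethod
    def default(cls, n_chroms: int = 5, length: int = 5_000_000) -> "SyntheticReference":
        return cls({f"chr{i + 1}": length for i in range(n_chroms)})

    def sequence(self, chrom: str) -> str:
        rng = np.random.default_rng(abs(hash(chrom)) % (2**31))
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, self.lengths[chrom])])


@dataclass
class ReadSimConfig:
    """Read-simulation conditions.

    Coverage presets 50x / 100x / 250x over a ~13x diploid background give
    amplicon copy numbers of roughly 7.7, 15.4 and 38.5 (CN = 2 * coverage /
    background).  Read lengths are log-normal with a 10 kb median (typical
    long-read profile), capped at 100 kb and at the circle length.
    """

    amplicon_coverage: float = 50.0
    background_coverage: float = 13.0
    read_length_median: float = 10_000.0
    read_length_sigma: float = 0.55
    read_length_min: int = 500
    read_length_max: int = 100_000
    breakend_jitter: int = 20
    junction_fn_rate: float = 0.02
    min_anchor: int = 50
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.amplicon_coverage < 0 or self.background_coverage <= 0:
            raise ValueError("coverages must be positive (amplicon may be 0)")

    def amplicon_cn(self) -> float:
        return 2.0 * self.amplicon_coverage / self.background_coverage


COVERAGE_PRESETS = (50.0, 100.0, 250.0)


@dataclass
class SimulatedAmplicon:
    """Ground truth for one circular amplicon."""

    mechanism: str
    cycle: list[Segment]
    n_breakpoints: int
    copy_number: float = 10.0
    amplicon_id: int = 1

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        self.cycle = _normalize_cycle(self.cycle)

    @property
    def cycle_length(self) -> int:
        return sum(e - s + 1 for _, s, e, _ in self.cycle)

    @property
    def span(self) -> tuple[str, int, int]:
        chrom = self.cycle[0][0]
        return (
            chrom,
            min(s for c, s, e, o in self.cycle if c == chrom),
            max(e for c, s, e, o in self.cycle if c == chrom),
        )

    def junctions(self) -> list[tuple[Breakend, Breakend]]:
        return _cycle_junctions(self.cycle)

    @property
    def true_graph(self) -> BreakpointGraph:
        return build_truth_graph(self.cycle, self.copy_number, self.amplicon_id)

    def true_cycle_record(self) -> CycleRecord:
        return CycleRecord(
            index=1, copy_number=self.copy_number, is_cycle=True, segments=list(self.cycle)
        )


# ---------------------------------------------------------------------------
# Cycle geometry
# ---------------------------------------------------------------------------


def _normalize_cycle(cycle: list[Segment]) -> list[Segment]:
    """Merge reference-contiguous same-orientation neighbours (cyclically)
    and rotate so the smallest segment comes first."""
    segs = [tuple(s) for s in cycle]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i in range(len(segs)):
            c1, s1, e1, o1 = segs[i]
            c2, s2, e2, o2 = segs[(i + 1) % len(segs)]
            if c1 == c2 and o1 == o2:
                if o1 == "+" and s2 == e1 + 1:
                    merged = (c1, s1, e2, "+")
                elif o1 == "-" and e2 == s1 - 1:
                    merged = (c1, s2, e1, "-")
                else:
                    continue
                if i + 1 < len(segs):
                    segs = segs[:i] + [merged] + segs[i + 2 :]
                else:
                    segs = [merged] + segs[1:-1]
                changed = True
                break
    pivot = segs.index(min(segs))
    return segs[pivot:] + segs[:pivot]


def _cycle_junctions(cycle: list[Segment]) -> list[tuple[Breakend, Breakend]]:
    """Breakend pairs between consecutive oriented segments (cyclically),
    skipping plain reference adjacencies."""
    from .intervals import is_concordant_pair

    out = []
    n = len(cycle)
    for i in range(n):
        c1, s1, e1, o1 = cycle[i]
        c2, s2, e2, o2 = cycle[(i + 1) % n]
        a = Breakend(c1, e1, "+") if o1 == "+" else Breakend(c1, s1, "-")
        b = Breakend(c2, s2, "-") if o2 == "+" else Breakend(c2, e2, "+")
        if not is_concordant_pair(a, b):
            out.append((a, b))
    return out


def build_truth_graph(
    cycle: list[Segment], copy_number: float, amplicon_id: int = 1, background_cn: float = 2.0
) -> BreakpointGraph:
    """Exact breakpoint graph of a circular structure at *copy_number*
    over a diploid background; balanced by construction."""
    from .intervals import canonical_pair, is_concordant_pair

    bounds: dict[str, set[int]] = {}
    for chrom, s, e, _ in cycle:
        bounds.setdefault(chrom, set()).update((s - 1, e))
    atoms: list[tuple[str, int, int]] = []
    for chrom, cuts in sorted(bounds.items()):
        pts = sorted(cuts)
        for a, b in zip(pts, pts[1:]):
            atoms.append((chrom, a + 1, b))
    # keep only atoms covered by some cycle segment
    def covered(atom):
        c, s, e = atom
        return any(c == cc and s >= ss and e <= ee for cc, ss, ee, _ in cycle)

    atoms = [a for a in atoms if covered(a)]
    atom_mult = {a: 0 for a in atoms}
    adj_count: dict[tuple[str, int], int] = {}
    for chrom, s, e, o in cycle:
        inside = [a for a in atoms if a[0] == chrom and a[1] >= s and a[2] <= e]
        inside.sort(key=lambda a: a[1])
        for a in inside:
            atom_mult[a] += 1
        for a, b in zip(inside, inside[1:]):
            adj_count[(chrom, a[2])] = adj_count.get((chrom, a[2]), 0) + 1

    junc_mult: dict[tuple, int] = {}
    for a, b in _cycle_junctions(cycle):
        key = canonical_pair(a, b)
        junc_mult[key] = junc_mult.get(key, 0) + 1

    graph = BreakpointGraph(amplicon_id=amplicon_id)
    for chrom, s, e in atoms:
        graph.add(
            SequenceEdge(chrom, s, e, cn=background_cn + copy_number * atom_mult[(chrom, s, e)])
        )
    # concordant edges between reference-adjacent atoms
    atoms_sorted = sorted(atoms)
    atom_set = set(atoms)
    for i, (chrom, s, e) in enumerate(atoms_sorted[:-1]):
        nxt = atoms_sorted[i + 1]
        if nxt[0] == chrom and nxt[1] == e + 1:
            graph.add(
                ConcordantEdge(
                    chrom, e, cn=background_cn + copy_number * adj_count.get((chrom, e), 0)
                )
            )
    for (a, b), mult in sorted(junc_mult.items()):
        graph.add(DiscordantEdge(a, b, cn=copy_number * mult, max_multiplicity=max(1, mult)))

    # source edges absorb the residual at each contiguous run's extremes
    from .model import balance_residual

    runs: list[list[tuple[str, int, int]]] = []
    for atom in atoms_sorted:
        if runs and runs[-1][-1][0] == atom[0] and runs[-1][-1][2] + 1 == atom[1]:
            runs[-1].append(atom)
        else:
            runs.append([atom])
    for run in runs:
        graph.add(SourceEdge("s", Breakend(run[0][0], run[0][1], "-")))
        graph.add(SourceEdge("t", Breakend(run[-1][0], run[-1][2], "+")))
    graph.sort()
    for edge in graph.source_edges:
        node = edge.nodes()[1]
        edge.cn = 0.0
        edge.cn = -balance_residual(graph, node)
        if edge.cn < -1e-9:
            raise AssertionError(f"negative source flow at {node}")
        edge.cn = max(edge.cn, 0.0)
    return graph


# ---------------------------------------------------------------------------
# Structure simulation
# ---------------------------------------------------------------------------


def _partition(total: int, k: int, min_len: int, rng) -> list[int]:
    """k positive lengths summing to total, each >= min_len."""
    if k * min_len > total:
        raise ValueError(f"cannot cut {total} bp into {k} fragments of >= {min_len} bp")
    extra = total - k * min_len
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1)) if k > 1 else np.array([], int)
    parts = np.diff(np.concatenate(([0], cuts, [extra])))
    return [int(p) + min_len for p in parts]


MIN_SEG = 5_000


def _apply_sv(cycle: list[Segment], kind: str, rng, chrom_len: int) -> list[Segment] | None:
    """One internal SV; returns None when no segment is large enough."""
    order = rng.permutation(len(cycle))
    for idx in order:
        chrom, s, e, o = cycle[int(idx)]
        length = e - s + 1
        if kind == "deletion" and length >= 3 * MIN_SEG:
            d1 = int(rng.integers(s + MIN_SEG, e - 2 * MIN_SEG + 1))
            d2 = int(rng.integers(d1 + MIN_SEG, e - MIN_SEG + 1))
            pieces = [(chrom, s, d1 - 1, "+"), (chrom, d2, e, "+")]
        elif kind == "duplication" and length >= 3 * MIN_SEG:
            d1 = int(rng.integers(s + MIN_SEG, e - 2 * MIN_SEG + 1))
            d2 = int(rng.integers(d1 + MIN_SEG, e - MIN_SEG + 1))
            pieces = [(chrom, s, d2, "+"), (chrom, d1, e, "+")]
        elif kind == "inversion" and length >= 3 * MIN_SEG:
            d1 = int(rng.integers(s + MIN_SEG, e - 2 * MIN_SEG + 1))
            d2 = int(rng.integers(d1 + MIN_SEG, e - MIN_SEG + 1))
            pieces = [(chrom, s, d1 - 1, "+"), (chrom, d1, d2, "-"), (chrom, d2 + 1, e, "+")]
        elif kind == "insertion" and length >= 2 * MIN_SEG:
            hi = max(ee for cc, ss, ee, oo in cycle if cc == chrom)
            don_s = hi + int(rng.integers(10_000, 40_000))
            don_len = int(rng.integers(MIN_SEG, 4 * MIN_SEG))
            if don_s + don_len > chrom_len:
                continue
            p = int(rng.integers(s + MIN_SEG, e - MIN_SEG + 1))
            pieces = [
                (chrom, s, p, "+"),
                (chrom, don_s, don_s + don_len - 1, "+"),
                (chrom, p + 1, e, "+"),
            ]
        else:
            continue
        if o == "-":
            pieces = [(c, a, b, "-" if oo == "+" else "+") for c, a, b, oo in reversed(pieces)]
        return cycle[: int(idx)] + pieces + cycle[int(idx) + 1 :]
    return None


def simulate_structure(
    reference: SyntheticReference,
    mechanism: str,
    n_breakpoints: int,
    rng: np.random.Generator,
    chrom: str | None = None,
    interval_length: int | None = None,
) -> SimulatedAmplicon:
    """Draw one circular amplicon structure with roughly *n_breakpoints*
    junctions from the given formation mechanism plus internal SVs."""
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}")
    if not 1 <= n_breakpoints <= 20:
        raise ValueError("n_breakpoints must lie in [1, 20]")
    chrom = chrom or str(rng.choice(sorted(reference.lengths)))
    chrom_len = reference.lengths[chrom]

    if mechanism == "chromothripsis":
        # keep the retained fragments' aggregate length comfortably focal
        # (well above typical seed-size thresholds)
        retention = rng.uniform(0.5, 0.9)
        keep = max(2, min(n_breakpoints, 20))
        n_frag = max(keep + 1, int(round(keep / retention)))
        min_frag = max(MIN_SEG, 130_000 // keep + 1)
        needed = int(n_frag * min_frag * 1.3)
        interval_length = max(interval_length or 0, needed)
    else:
        interval_length = interval_length or int(rng.integers(150_000, 350_000))
    if interval_length + 200_000 > chrom_len:
        raise ValueError(
            f"interval length {interval_length} does not fit on {chrom} ({chrom_len} bp)"
        )
    start = int(rng.integers(100_000, chrom_len - interval_length - 100_000))
    end = start + interval_length - 1

    if mechanism == "episomal":
        cycle: list[Segment] = [(chrom, start, end, "+")]
    elif mechanism == "2-foldback":
        cycle = [(chrom, start, end, "+"), (chrom, start, end, "-")]
    else:  # chromothripsis
        lengths = _partition(interval_length, n_frag, min_frag, rng)
        frags = []
        pos = start
        for L in lengths:
            frags.append((chrom, pos, pos + L - 1))
            pos += L
        idx = rng.permutation(n_frag)[:keep]
        cycle = []
        for i in idx:
            c, s, e = frags[int(i)]
            o = "+" if rng.random() < 0.5 else "-"
            cycle.append((c, s, e, o))

    cycle = _normalize_cycle(cycle)
    n_junc = len(_cycle_junctions(cycle))
    sv_kinds = ["deletion", "duplication", "inversion", "insertion"]
    attempts = 0
    while n_junc < n_breakpoints and attempts < 50:
        attempts += 1
        kind = sv_kinds[int(rng.integers(0, len(sv_kinds)))]
        edited = _apply_sv(cycle, kind, rng, chrom_len)
        if edited is None:
            continue
        edited = _normalize_cycle(edited)
        nj = len(_cycle_junctions(edited))
        if nj <= n_breakpoints and nj > n_junc:
            cycle, n_junc = edited, nj
    if n_junc == 0:
        raise ValueError(f"mechanism {mechanism} produced no junctions")
    return SimulatedAmplicon(mechanism=mechanism, cycle=cycle, n_breakpoints=n_junc)


# ---------------------------------------------------------------------------
# Alignment-level read simulation
# ---------------------------------------------------------------------------


@dataclass
class _Rec:
    qname: str
    chrom: str
    pos1: int  # 1-based leftmost
    strand: str
    match_len: int
    clip_left: int
    clip_right: int
    supplementary: bool = False

    def cigar(self) -> str:
        out = []
        if self.clip_left:
            out.append(f"{self.clip_left}S")
        out.append(f"{self.match_len}M")
        if self.clip_right:
            out.append(f"{self.clip_right}S")
        return "".join(out)


def _read_lengths(total_bases: float, cfg: ReadSimConfig, rng, cap: int) -> list[int]:
    lengths: list[int] = []
    mu = np.log(cfg.read_length_median)
    acc = 0.0
    while acc < total_bases:
        L = int(np.exp(rng.normal(mu, cfg.read_length_sigma)))
        L = max(cfg.read_length_min, min(L, cfg.read_length_max, cap))
        lengths.append(L)
        acc += L
    return lengths


def _amplicon_pieces(amplicon: SimulatedAmplicon, start: int, length: int):
    """Reference pieces (chrom, ref_start, ref_end, strand) of a read of
    *length* bases beginning at circular offset *start*."""
    offsets = []
    off = 0
    for seg in amplicon.cycle:
        offsets.append((off, seg))
        off += seg[2] - seg[1] + 1
    L_cyc = amplicon.cycle_length
    pieces = []
    pos = start % L_cyc
    left = length
    while left > 0:
        for o, (chrom, s, e, strand) in offsets:
            seg_len = e - s + 1
            if o <= pos < o + seg_len:
                take = min(left, o + seg_len - pos)
                d = pos - o
                if strand == "+":
                    pieces.append((chrom, s + d, s + d + take - 1, "+"))
                else:
                    pieces.append((chrom, e - d - take + 1, e - d, "-"))
                pos = (pos + take) % L_cyc
                left -= take
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("circular offset out of range")
    return pieces


def _amplicon_records(
    amplicon: SimulatedAmplicon, cfg: ReadSimConfig, rng
) -> list[_Rec]:
    L_cyc = amplicon.cycle_length
    total = cfg.amplicon_coverage * L_cyc
    records: list[_Rec] = []
    if total <= 0:
        return records
    for ridx, L in enumerate(_read_lengths(total, cfg, rng, L_cyc)):
        start = int(rng.integers(0, L_cyc))
        pieces = _amplicon_pieces(amplicon, start, L)
        # breakend jitter: move each internal junction by a few bases
        jittered = []
        for i, (chrom, s, e, strand) in enumerate(pieces):
            s2, e2 = s, e
            if i > 0 and cfg.breakend_jitter:
                j = int(rng.integers(-cfg.breakend_jitter, cfg.breakend_jitter + 1))
                if strand == "+":
                    s2 = s + j
                else:
                    e2 = e - j
            if i < len(pieces) - 1 and cfg.breakend_jitter:
                j = int(rng.integers(-cfg.breakend_jitter, cfg.breakend_jitter + 1))
                if strand == "+":
                    e2 = e + j
                else:
                    s2 = s - j
            if e2 - s2 + 1 >= cfg.min_anchor and s2 >= 1:
                jittered.append((chrom, s2, e2, strand))
        pieces = jittered
        if not pieces:
            continue
        # junction false negatives: truncate the read at a dropped junction
        if len(pieces) > 1 and cfg.junction_fn_rate > 0:
            for i in range(1, len(pieces)):
                if rng.random() < cfg.junction_fn_rate:
                    pieces = pieces[:i]
                    break
        qlens = [e - s + 1 for _, s, e, _ in pieces]
        qtotal = sum(qlens)
        qname = f"amp{amplicon.amplicon_id}_r{ridx}"
        qoff = 0
        for i, (chrom, s, e, strand) in enumerate(pieces):
            ml = qlens[i]
            if strand == "+":
                cl, cr = qoff, qtotal - qoff - ml
            else:
                cl, cr = qtotal - qoff - ml, qoff
            records.append(
                _Rec(qname, chrom, s, strand, ml, cl, cr, supplementary=i > 0)
            )
            qoff += ml
    return records


def _background_records(
    reference: SyntheticReference, cfg: ReadSimConfig, rng
) -> list[_Rec]:
    records: list[_Rec] = []
    for chrom in sorted(reference.lengths):
        clen = reference.lengths[chrom]
        for ridx, L in enumerate(
            _read_lengths(cfg.background_coverage * clen, cfg, rng, clen)
        ):
            start = int(rng.integers(1, max(2, clen - L + 1)))
            records.append(_Rec(f"bg_{chrom}_r{ridx}", chrom, start, "+", L, 0, 0))
    return records


def _write_bam(records: list[_Rec], reference: SyntheticReference, out_prefix) -> str:
    """Write sorted, indexed BAM; returns its path."""
    refs = sorted(reference.lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": reference.lengths[c]} for c in refs],
    }
    by_read: dict[str, list[_Rec]] = {}
    for r in records:
        by_read.setdefault(r.qname, []).append(r)
    unsorted_path = str(out_prefix) + ".unsorted.bam"
    bam_path = str(out_prefix) + ".bam"
    with pysam.AlignmentFile(unsorted_path, "wb", header=header) as bam:
        tid = {c: i for i, c in enumerate(refs)}
        for qname, group in by_read.items():
            sa_parts = [
                f"{r.chrom},{r.pos1},{r.strand},{r.cigar()},60,0;" for r in group
            ]
            for i, r in enumerate(group):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.reference_id = tid[r.chrom]
                a.reference_start = r.pos1 - 1
                a.mapping_quality = 60
                a.cigarstring = r.cigar()
                flag = 0
                if r.strand == "-":
                    flag |= 16
                if r.supplementary:
                    flag |= 2048
                a.flag = flag
                if len(group) > 1:
                    sa = "".join(sa_parts[:i] + sa_parts[i + 1 :])
                    a.set_tag("SA", sa)
                bam.write(a)
    pysam.sort("-o", bam_path, unsorted_path)
    pysam.index(bam_path)
    import os

    os.unlink(unsorted_path)
    return bam_path


def simulate_alignments(
    amplicons,
    reference: SyntheticReference,
    config: ReadSimConfig,
    rng: np.random.Generator,
    out_prefix,
) -> str:
    """Simulate mapped reads for one or more amplicons plus the diploid
    background and write a sorted, indexed BAM.  Deterministic under the
    supplied generator."""
    if isinstance(amplicons, SimulatedAmplicon):
        amplicons = [amplicons]
    records: list[_Rec] = []
    for amp in amplicons:
        records.extend(_amplicon_records(amp, config, rng))
    records.extend(_background_records(reference, config, rng))
    return _write_bam(records, reference, out_prefix)


# ---------------------------------------------------------------------------
# Truth CNV table and dataset assembly
# ---------------------------------------------------------------------------


def truth_cnv_segments(
    amplicons: list[SimulatedAmplicon],
    reference: SyntheticReference,
    config: ReadSimConfig,
) -> list[CNVSegment]:
    """Expected CNV calls: per-atom CN from the truth graphs over a CN-2
    background, with coverage = (background_coverage / 2) * CN."""
    per_copy = config.background_coverage / 2.0
    by_chrom: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in reference.lengths
    }
    for amp in amplicons:
        for e in amp.true_graph.sequence_edges:
            by_chrom[e.chrom].append((e.start, e.end, e.cn))
    out: list[CNVSegment] = []
    for chrom in sorted(reference.lengths):
        clen = reference.lengths[chrom]
        amp_segs = sorted(by_chrom[chrom])
        pos = 1
        for s, e, cn in amp_segs:
            if s > pos:
                out.append(CNVSegment(chrom, pos, s - 1, 2.0, 2.0 * per_copy))
            out.append(CNVSegment(chrom, s, e, cn, cn * per_copy))
            pos = e + 1
        if pos <= clen:
            out.append(CNVSegment(chrom, pos, clen, 2.0, 2.0 * per_copy))
    return out


def write_cnv_table(segments: list[CNVSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tcn\tdepth\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.cn:.4f}\t{s.mean_coverage:.4f}\n")


@dataclass
class TestDataset:
    """One simulated test data set plus its serialized truth bundle."""

    bam_path: str
    cnv_path: str
    amplicons: list[SimulatedAmplicon]
    manifest_path: str
    truth_graph_paths: list[str]
    truth_cycles_paths: list[str]
    reference: SyntheticReference
    config: ReadSimConfig


def make_test_dataset(
    pool: list[SimulatedAmplicon],
    n_amplicons: int,
    coverage_preset: float,
    rng: np.random.Generator,
    out_dir,
    reference: SyntheticReference | None = None,
    config: ReadSimConfig | None = None,
    name: str = "dataset",
) -> TestDataset:
    """Select amplicons from *pool*, simulate merged alignments at the given
    coverage preset and write the truth bundle (graphs, cycles, CNV table,
    JSON manifest)."""
    import os

    if not 1 <= n_amplicons <= 5:
        raise ValueError("n_amplicons must lie in [1, 5]")
    reference = reference or SyntheticReference.default()
    config = config or ReadSimConfig()
    config = replace(config, amplicon_coverage=float(coverage_preset))
    chosen_idx = rng.choice(len(pool), size=n_amplicons, replace=False)
    chosen = [pool[int(i)] for i in sorted(chosen_idx)]
    spans = [a.span for a in chosen]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            a, b = spans[i], spans[j]
            if a[0] == b[0] and not (a[2] + 50_000 < b[1] or b[2] + 50_000 < a[1]):
                raise ValueError(f"amplicon source regions overlap: {a} vs {b}")
    os.makedirs(out_dir, exist_ok=True)
    amps = []
    for i, amp in enumerate(chosen, start=1):
        amps.append(
            replace_amplicon(amp, amplicon_id=i, copy_number=config.amplicon_cn())
        )
    bam = simulate_alignments(amps, reference, config, rng, os.path.join(out_dir, name))
    cnv_path = os.path.join(out_dir, f"{name}_cnv.tsv")
    write_cnv_table(truth_cnv_segments(amps, reference, config), cnv_path)
    gpaths, cpaths = [], []
    for amp in amps:
        gp = os.path.join(out_dir, f"{name}_truth_amplicon{amp.amplicon_id}_graph.txt")
        cp = os.path.join(out_dir, f"{name}_truth_amplicon{amp.amplicon_id}_cycles.txt")
        write_graph(amp.true_graph, gp)
        write_cycles([amp.true_cycle_record()], cp)
        gpaths.append(gp)
        cpaths.append(cp)
    manifest = {
        "name": name,
        "coverage": config.amplicon_coverage,
        "background_coverage": config.background_coverage,
        "amplicons": [
            {
                "id": a.amplicon_id,
                "mechanism": a.mechanism,
                "n_breakpoints": a.n_breakpoints,
                "copy_number": a.copy_number,
                "span": list(a.span),
            }
            for a in amps
        ],
    }
    mpath = os.path.join(out_dir, f"{name}_manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return TestDataset(bam, cnv_path, amps, mpath, gpaths, cpaths, reference, config)


def replace_amplicon(amp: SimulatedAmplicon, **kw) -> SimulatedAmplicon:
    return SimulatedAmplicon(
        mechanism=amp.mechanism,
        cycle=list(amp.cycle),
        n_breakpoints=amp.n_breakpoints,
        copy_number=kw.get("copy_number", amp.copy_number),
        amplicon_id=kw.get("amplicon_id", amp.amplicon_id),
    )
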