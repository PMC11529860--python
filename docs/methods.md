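# Methods

This note records the models, numerical choices and open design decisions
behind `ecrecon`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Breakpoint graph

A per-amplicon graph `G = (V, Es ∪ Ec ∪ Ed, CN)` over 1-based inclusive
reference coordinates (BAM's 0-based half-open coordinates are converted at
ingestion). Nodes are segment endpoints plus the source/sink pair `s`, `t`.
Breakend orientation follows the standard SV convention: `+` leaves a
segment at its higher coordinate, `-` at its lower; a foldback has both
breakends at the same locus with equal orientation and counts **twice**
toward the balance sum at its node, because a traversal both enters and
leaves through it — without this the balance equation cannot close on
inverted duplications.

Copy numbers are balanced: at each endpoint of every sequence edge, the
summed CN of incident breakpoint-class edges (concordant + discordant +
source) equals the sequence edge's CN. CN is stored as double precision;
the default post-fit balance tolerance is 1e-4 (the balance requirement is
an exact equality in the model; the tolerance only absorbs optimizer
round-off and is configurable).

## 2. Interval search

Seeds come from a CNV segment table (CNVkit-style). A seed is a maximal run
of amplified segments (`cn ≥ seed_cn_min`, default 5.0) whose **amplified**
aggregate length reaches `seed_size_min` (default 50 kb). Unamplified gaps
up to `seed_gap_max` (default 100 kb) do not break a run: shattered
(chromothripsis-like) amplicons present as interleaved high/low CN segments
and would otherwise never seed; only amplified bases count toward the
aggregate, and the emitted seed spans the run. The gap tolerance matches
the interval-padding scale δ.

BFS discovery: seeds are padded by δ (default 100 kb, clamped to chromosome
bounds) so junction breakends jittered across a seed boundary stay inside
an interval. Each popped interval's chimeric alignments yield breakend
pairs; these are greedily clustered (sorted sweep per orientation
signature, window 100 bp — matching the 100 bp evaluation tolerance — new
cluster when either breakend strays beyond the window from the cluster
median; representative = member median). Clusters need support of at least
the haploid coverage, operationalized as `max(3, round(θ/2))` reads with a
floor for low-coverage runs (global θ; the local alternative is noted but
not used). A sufficiently supported far locus either lands in an existing
interval (connection label) or opens a new one: `[max(s_l−δ, l−Δ),
min(e_l+δ, l+Δ)]` inside an amplified CNV segment `[s_l, e_l]`, else
`[l−δ, l+δ]`, with Δ = 2 Mb. Discovery order is deterministic: FIFO over
intervals, clusters by descending support then coordinate.

After BFS, intervals merge when overlapping/adjacent or when on the same
chromosome within 2δ of a breakpoint connection; merging unifies amplicons.
Breakpoints are then re-extracted across each merged amplicon (each read
counted once; junctions must have both breakends inside the amplicon's
intervals — observations leaving the intervals are counted and logged).

Graph assembly: cut positions derive from breakends (`+` at p cuts after p,
`-` at p cuts after p−1). Cuts within `cut_merge_window` (50 bp) snap to a
support-weighted consensus and the contributing breakends are rewritten to
agree. This matters for inversions: their two breakends straddle the same
boundary, and placement noise would otherwise leave a few-bp sliver segment
whose nodes carry no junction, forcing concordant CN to equal sequence CN
and skewing the whole fit. Sequence edges tile each interval exactly;
concordant edges join adjacent sequence edges; `s` attaches at each
interval's smallest coordinate and `t` at its largest.

## 3. Copy-number assignment

θ is the diploid coverage, estimated as the coverage of the segment at the
40th percentile of CNV segments sorted by called CN, with nearest rank
**weighted by segment length** — by count, a fragmented amplicon's many
short segments can displace the diploid bulk; on equal-length segments the
two definitions coincide.

Per-copy coverage is θ/2 (a CN-2 segment shows coverage θ). Observed
nucleotide totals on sequence edges are Normal with mean = variance =
(θ/2)·CN·l; junction read counts are Poisson with mean (θ/2)·CN. A read
supports a concordant edge only when it extends ≥ 50 bp on both sides of
the junction, so breakend jitter on split reads is not mistaken for
read-through. The joint likelihood is maximized under hard balance
equalities and CN ≥ 0; source edges are observation-free free variables.
The Normal term with CN inside the variance is non-concave, so we optimize
the smooth objective from a method-of-moments start (trust-region with
analytic gradients), floor CN at 1e-6 to keep logs finite, and clamp
floor-level components to zero. Balance is asserted post hoc; failure
raises with the worst node's residual.

## 4. Cycle extraction

Walks alternate sequence and breakpoint edges; a cycle is a closed
alternating sequence avoiding `s`, `t`; an s–t walk starts at `s` and ends
at `t`. The full mode minimizes
`Σ z_i − (1/C_l(G))·Σ w_i x_uvi l(u,v) − (1/m)·Σ P_j` over at most `k`
walks subject to: `w_i ≤ z_i·C_l(G)` with a positive weight floor
(1e-6 × the largest edge CN); explained mass ≥ α·C_l(G) and satisfied
subwalks ≥ β·m (α = β = 0.9); per-edge capacity `Σ_i w_i x_uvi ≤ CN`;
discordant multiplicity caps R(u,v); per-node class balance (sequence
incidences = breakpoint incidences per walk, foldbacks twice); exactly one
s-edge and one t-edge for s–t walks; and connectivity.

**Connectivity.** Rather than discovery-order (MTZ-style) node numbering we
require each walk's support subgraph to be connected with a
single-commodity flow (binary used-edge/used-node indicators, one root per
active walk, each used node sinks one flow unit). Per-node class balance
plus connectivity is necessary *and sufficient* for the multiplicities to
form a single alternating closed trail: a Hierholzer argument applies
because any closed alternating sub-circuit through a shared node can be
spliced between that node's in/out edges after an orientation flip. The
trail itself is rebuilt deterministically by exactly that splicing sweep.

**Exact linearization.** The bilinear `w_i·x_uvi` terms are expanded over
the binary digits of `x_uvi` (bounded by the per-edge caps) and each
bit–weight product is a McCormick envelope, which is exact when one factor
is binary. The resulting MILP is solved with HiGHS (single-threaded,
deterministic variable order; symmetry broken by ordering the `z_i`).

**Caps.** R(u,v) for a discordant edge: with read support, the edge's
support divided by the amplicon's median junction support (the typical
once-traversed level), rounded, floored at 1, capped at 5; without read
data, `ceil(CN_e / max discordant CN)`. Concordant edges cap at 4 per walk;
a sequence edge caps at the breakpoint-incidence budget of its scarcer
endpoint. These caps also bound the binary expansions.

**Greedy mode** extracts one walk at a time maximizing
`Σ w·x·l + γ·Σ_{j∈P̄} P_j` with `γ = 0.01·C_l(residual)/|P̄|`, removes its
copy number from the residual graph, and stops when α·C_l(G) mass and β·m
constraints are explained or the next walk's **length-weighted** copy
number falls below ε·C_l(G) (ε = 0.005; on unit-length segments this is
the walk's copy number, which is how the stopping rule is usually quoted).

**Driver.** Full mode when |E| ≤ 100, starting at k = 10 and doubling on
infeasibility until k > |E| or the estimated variable count exceeds 10,000,
then greedy; optional post-processing re-solves full mode at
α′ = min(0.9, 1 − C_l(residual)/C_l(G)), β′ = min(0.9, 1 − |P̄|/|P|). Walks
are sorted by length-weighted CN, cycles canonicalized (rotation to the
smallest coordinate, forward-reading first segment) for stable comparison.

**Subwalk constraints.** A chimeric read qualifies when its chain crosses
≥ 2 junction (concordant or discordant) edges of which ≥ 1 is discordant —
the worked duplication example's read crosses
concordant–discordant–concordant, while plain reads crossing segment
boundaries never qualify. Chains are canonicalized (a chain equals its
reverse) and deduplicated with support counts. Satisfaction uses weak
*subgraph* semantics — every chain edge present in the walk with at least
the chain's multiplicity — matching the constraint actually imposed in the
optimization; an ordered-walk semantics switch is left as future work and
the flag is reserved in the config.

## 5. Simulator

The generator emulates the study conditions at desk scale: circular
structures from three mechanisms (episomal excision; chromothripsis with
fragment retention 0.5–0.9, shuffling and reorientation; head-to-head
2-foldback duplication) edited with 0–n internal SVs (deletion,
duplication, inversion, insertion of a nearby donor) until a target
junction count in [1, 20] is reached; segment arithmetic keeps every piece
≥ 5 kb and the retained chromothripsis mass ≥ ~130 kb so amplicons remain
focal and seedable. The exact breakpoint graph of each structure (over a
CN-2 diploid background, source edges absorbing boundary flow) is emitted
as ground truth and is balanced by construction.

Reads are simulated at the **alignment level**: start positions uniform on
the circle at the amplicon coverage preset (50×/100×/250× over a 13×
diploid background, i.e. amplicon CN = 2·coverage/13 ≈ 7.7/15.4/38.5) and
uniform on the linear reference at the background coverage; lengths
log-normal (median 10 kb, σ = 0.55, min 500 bp, capped at 100 kb and the
circle length). Junction-crossing reads become primary + supplementary
records with correct clip sides, strands and `SA` tags. Sequencing and
mapping error reduce to breakend jitter (±20 bp uniform per junction side),
a 2% junction false-negative rate (read truncated at the dropped junction)
and a 50 bp minimum anchor. The synthetic reference is a table of
chromosome lengths (default 5 × 5 Mb; base-level sequence is never needed,
though a deterministic sequence generator is provided). Not emulated: base
errors and homopolymer artifacts, repeats/low-complexity mapping ambiguity,
GC bias, multiple germline backgrounds, tumor purity. Passing tests
therefore demonstrate correctness of the graph/CN/cycle machinery under
idealized mapping, not robustness to alignment artifacts on real genomes.

## 6. Evaluation metrics

* **Breakpoint-graph accuracy** — fraction of truth discordant edges
  matched under maximum bipartite (one-to-one) matching, both breakends
  within 100 bp and orientations equal. One-to-one prevents a single
  reconstructed edge matching several truth edges.
* **Cycle interval overlap** — nucleotide-weighted Jaccard of covered
  reference intervals, multiplicity ignored.
* **Cyclic LCS** — segments matched between cycles at the breakend
  tolerance, unshared segments eliminated, then the length-weighted LCS of
  oriented tokens maximized over rotations of both cycles and orientation
  flips of the reconstruction (cycles have no canonical start or strand;
  an orientation-insensitive mode is available), normalized by the truth
  cycle's nucleotide length.
* **Length error** — `log2(|len_r − len_t|/len_t + 1e-6)`; the floor guards
  the −∞ of an exact match, which is additionally flagged. The absolute
  difference is used; the sign is recoverable from the lengths.

## 7. Problem sizes and determinism

The shipped tests and the acceptance script run the worked examples
(7–8 edges), an exhaustive-enumeration equivalence check on 25 random
graphs with ≤ 6 edges and integer CN ≤ 8, copy-number recovery at the three
coverage presets, and a 30-amplicon mixed-mechanism simulation suite on a
1.5 Mb synthetic chromosome — sizes chosen so the whole suite completes in
minutes on one CPU while exercising every code path, including solver
k-doubling and the greedy fallback. All randomness flows through seeded
`numpy` generators; the MILP backend runs single-threaded with fixed
variable order, so reruns are bit-reproducible.

## 8. Known limitations

* The likelihood convention sets per-copy coverage to θ/2 so that diploid
  regions have CN 2; junction support is biased a few percent low relative
  to nucleotide coverage (anchors, false negatives), which the balance
  constraint redistributes rather than models explicitly.
* Full-mode feasibility at α = 0.9 is sensitive to coverage fluctuation at
  the 10 kb read scale (source-edge capacity follows local flank coverage);
  infeasible instances fall back to greedy by design.
* Two genuinely distinct junctions closer than the 50 bp cut-snapping
  window would be merged; simulated segments are kept ≥ 5 kb, and real
  ecDNA junctions this close are rare but possible.
* Germline SV filtering against a matched normal, GC/mappability
  correction, and tumor-purity deconvolution are out of scope.
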