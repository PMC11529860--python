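import numpy as np
import pytest

from ecrecon.cycles import SubwalkConstraint, estimate_multiplicity_caps
from ecrecon.model import (
    Breakend,
    BreakpointGraph,
    ConcordantEdge,
    DiscordantEdge,
    SequenceEdge,
)


def make_abc_graph(cn_a: float, cn_b: float, cn_c: float, with_back_junction: bool):
    """Three unit-length segments A, B, C closed into circular architectures.

    Junctions: a duplication junction at B (end(B) -> start(B)), a closing
    junction end(C) -> start(A), and optionally a back junction
    end(B) -> start(A) enabling the plain A-B cycle.  Edge CNs follow from
    balance given the segment CNs.
    """
    g = BreakpointGraph(amplicon_id=1)
    A = SequenceEdge("chr1", 1, 1, cn=cn_a)
    B = SequenceEdge("chr1", 2, 2, cn=cn_b)
    C = SequenceEdge("chr1", 3, 3, cn=cn_c)
    c1 = ConcordantEdge("chr1", 1, cn=cn_a)
    c2 = ConcordantEdge("chr1", 2, cn=cn_c)
    d_dup = DiscordantEdge(Breakend("chr1", 2, "+"), Breakend("chr1", 2, "-"), cn=cn_c)
    d_close = DiscordantEdge(Breakend("chr1", 3, "+"), Breakend("chr1", 1, "-"), cn=cn_c)
    for e in (A, B, C, c1, c2, d_dup, d_close):
        g.add(e)
    if with_back_junction:
        g.add(
            DiscordantEdge(
                Breakend("chr1", 2, "+"), Breakend("chr1", 1, "-"), cn=cn_a - cn_c
            )
        )
    g.sort()
    estimate_multiplicity_caps(g)
    keys = {
        "A": A.key(),
        "B": B.key(),
        "C": C.key(),
        "c1": c1.key(),
        "c2": c2.key(),
        "d_dup": d_dup.key(),
        "d_close": d_close.key(),
    }
    return g, keys


def abbc_constraint(keys, graph_id=1) -> SubwalkConstraint:
    """The subwalk implied by one long read spanning A, B, B, C."""
    return SubwalkConstraint(
        0,
        [keys["A"], keys["c1"], keys["B"], keys["d_dup"], keys["B"], keys["c2"], keys["C"]],
        graph_id=graph_id,
    )


@pytest.fixture
def abc_single_cycle():
    """Worked three-segment graph whose only decomposition is one cycle of
    copy number 50 traversing B twice."""
    return make_abc_graph(50, 100, 50, with_back_junction=False)


@pytest.fixture
def abc_two_cycle():
    """Worked three-segment graph (CNs 90/100/10) whose optimum under the
    A-B-B-C subwalk constraint is cycles of copy number 80 and 10."""
    return make_abc_graph(90, 100, 10, with_back_junction=True)


@pytest.fixture(scope="session")
def episomal_dataset(tmp_path_factory):
    """A small noiseless-ish episomal amplicon dataset shared across tests."""
    from ecrecon.simulate import SyntheticReference, make_test_dataset, simulate_structure

    rng = np.random.default_rng(7)
    ref = SyntheticReference({"chr1": 1_500_000})
    amp = simulate_structure(ref, "episomal", 3, rng, chrom="chr1", interval_length=150_000)
    out = tmp_path_factory.mktemp("episomal_ds")
    ds = make_test_dataset([amp], 1, 50.0, rng, out, reference=ref, name="d1")
    return ds
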