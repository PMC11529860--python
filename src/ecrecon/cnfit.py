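"""Balanced maximum-likelihood copy-number assignment.

Let theta be the diploid long-read coverage, estimated as the coverage of
the segment at the 40th percentile of CNV segments sorted by their called
CN (most of the genome is unamplified, so this lands on a diploid segment).
The per-copy coverage is then theta / 2, and we model

* the total number of aligned nucleotides on a sequence edge (u, v) as
  Normal with mean = variance = (theta / 2) * CN(u, v) * l(u, v);
* the read count supporting each concordant / discordant edge as
  Poisson with mean (theta / 2) * CN(u, v).

CN over all edges jointly maximizes the log-likelihood subject to hard
balance equalities at every non-source node (source edges are free,
observation-less variables absorbing flow at amplicon boundaries) and
CN >= 0.  The objective is smooth but non-concave (CN enters the Normal
variance), so it is optimized from a method-of-moments start with CN
floored at a small positive value; components that end at the floor are
clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .model import (
    BreakpointGraph,
    DiscordantEdge,
    check_balance,
)

__all__ = ["CoverageModel", "CNFitError", "estimate_theta", "assign_cn"]

CN_FLOOR = 1e-6


class CNFitError(RuntimeError):
    """Raised when the constrained MLE cannot be solved."""


@dataclass
class CoverageModel:
    """Diploid coverage plus the per-edge observations driving the MLE."""

    theta: float
    balance_tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def per_copy(self) -> float:
        return self.theta / 2.0


def estimate_theta(segments) -> float:
    """Diploid coverage = observed coverage of the segment at the 40th
    percentile (nearest rank, weighted by segment length) after sorting
    segments by called CN.

    Length weighting keeps the estimate on unamplified genome even when the
    CNV table fragments an amplicon into many short high-CN segments; on
    equal-length segments it reduces to the plain nearest-rank percentile.
    """
    covs = [
        (s.cn, s.length, s.mean_coverage)
        for s in segments
        if s.mean_coverage == s.mean_coverage  # drop NaN
    ]
    if not covs:
        raise ValueError("no segments with observed coverage")
    covs.sort(key=lambda t: t[0])
    total = sum(length for _, length, _ in covs)
    target = 0.4 * total
    acc = 0
    theta = covs[-1][2]
    for _, length, cov in covs:
        acc += length
        if acc >= target:
            theta = cov
            break
    if theta <= 0:
        raise ValueError(f"non-positive coverage {theta} at the 40th percentile")
    return float(theta)


def _edge_index(graph: BreakpointGraph):
    edges = graph.all_edges()
    return edges, {id(e): i for i, e in enumerate(edges)}


def _balance_matrix(graph: BreakpointGraph, index) -> np.ndarray:
    """Rows = non-source nodes; A @ cn = 0 encodes the balance equalities."""
    from .model import incident_edges

    nodes = [n for n in graph.nodes if not n.is_source]
    A = np.zeros((len(nodes), len(index)))
    for r, node in enumerate(nodes):
        inc = incident_edges(graph, node)
        for e in inc["sequence"]:
            A[r, index[id(e)]] -= 1.0
        for e in inc["concordant"]:
            A[r, index[id(e)]] += 1.0
        for e in inc["discordant"]:
            mult = 2.0 if isinstance(e, DiscordantEdge) and e.is_foldback else 1.0
            A[r, index[id(e)]] += mult
    return A


def assign_cn(graph: BreakpointGraph, model: CoverageModel) -> BreakpointGraph:
    """Assign balanced maximum-likelihood copy numbers to every edge of
    *graph* in place (and return it)."""
    edges, index = _edge_index(graph)
    if not graph.sequence_edges:
        raise CNFitError("graph has no sequence edges")
    a = model.per_copy
    n = len(edges)

    # per-variable observation terms
    seq_scale = np.zeros(n)  # a * l for sequence edges
    seq_obs = np.zeros(n)
    poi_scale = np.zeros(n)  # a for junction edges with read counts
    poi_obs = np.zeros(n)
    is_seq = np.zeros(n, dtype=bool)
    is_poi = np.zeros(n, dtype=bool)
    from .model import ConcordantEdge, SequenceEdge

    for i, e in enumerate(edges):
        if isinstance(e, SequenceEdge):
            is_seq[i] = True
            seq_scale[i] = a * e.length
            seq_obs[i] = e.observed_nucleotides
        elif isinstance(e, (ConcordantEdge, DiscordantEdge)):
            is_poi[i] = True
            poi_scale[i] = a
            poi_obs[i] = float(e.read_support)
        # source edges: free, no observation term

    if not np.any(seq_obs > 0) and not np.any(poi_obs > 0):
        for e in edges:
            e.cn = 0.0
        return graph

    def neg_ll(cn: np.ndarray) -> float:
        mu_s = seq_scale[is_seq] * cn[is_seq]
        # (obs - mu)^2 / (2 mu) + 0.5 ln mu  ==  obs^2/(2 mu) - obs + mu/2 + 0.5 ln mu
        f = np.sum(
            seq_obs[is_seq] ** 2 / (2 * mu_s) + mu_s / 2.0 + 0.5 * np.log(mu_s)
        )
        mu_p = poi_scale[is_poi] * cn[is_poi]
        f += np.sum(mu_p - poi_obs[is_poi] * np.log(mu_p))
        return float(f)

    def grad(cn: np.ndarray) -> np.ndarray:
        g = np.zeros(n)
        mu_s = seq_scale[is_seq] * cn[is_seq]
        g[is_seq] = seq_scale[is_seq] * (
            0.5 - seq_obs[is_seq] ** 2 / (2 * mu_s**2) + 0.5 / mu_s
        )
        mu_p = poi_scale[is_poi] * cn[is_poi]
        g[is_poi] = poi_scale[is_poi] * (1.0 - poi_obs[is_poi] / mu_p)
        return g

    # method-of-moments start
    x0 = np.full(n, CN_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        x0[is_seq] = np.maximum(seq_obs[is_seq] / seq_scale[is_seq], CN_FLOOR)
        x0[is_poi] = np.maximum(poi_obs[is_poi] / poi_scale[is_poi], CN_FLOOR)
    A = _balance_matrix(graph, index)
    # start each source edge at the residual its node needs it to absorb
    for i, e in enumerate(edges):
        if is_seq[i] or is_poi[i]:
            continue
        col = A[:, i]
        rows = np.nonzero(col)[0]
        if len(rows):
            x0[i] = CN_FLOOR
            resid = -float(A[rows[0]] @ x0) / float(col[rows[0]])
            x0[i] = max(resid, CN_FLOOR)
    x0 = np.maximum(x0, CN_FLOOR)

    ub = max(10.0 * float(np.max(x0)), 100.0)
    constraints = [LinearConstraint(A, 0.0, 0.0)] if A.size else []
    import warnings

    with warnings.catch_warnings():
        # quasi-Newton curvature updates degenerate harmlessly on the
        # near-linear Poisson-only coordinates
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res = minimize(
            neg_ll,
            x0,
            jac=grad,
            method="trust-constr",
            bounds=[(CN_FLOOR, ub)] * n,
            constraints=constraints,
            options={"maxiter": 2000, "gtol": 1e-8, "xtol": 1e-12},
        )
    if res.x is None or not np.all(np.isfinite(res.x)):
        raise CNFitError(f"CN optimization failed: {res.message}")

    cn = np.asarray(res.x, dtype=float)
    cn[cn <= 2 * CN_FLOOR] = 0.0
    for i, e in enumerate(edges):
        e.cn = float(cn[i])

    violations = check_balance(graph, max(model.balance_tolerance, 1e-3 * float(np.max(cn, initial=1.0))))
    if violations:
        worst = max(violations, key=lambda v: abs(v[1]))
        raise CNFitError(
            f"CN fit did not converge to a balanced assignment; worst residual "
            f"{worst[1]:.4g} at node {worst[0]} ({len(violations)} nodes)"
        )
    return graph
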