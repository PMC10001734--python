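"""Intuitionistic-fuzzy AHP: expert weighting, aggregation, consistency, priorities.

The weighting stage proceeds in phases: (1) each panel member receives a
relative weight from their knowledge-degree IFN; (2) per-expert pairwise
judgment matrices are pooled cell-wise with the IFWA operator; (3) the
aggregated matrix is checked for consistency via Saaty's consistency ratio
on a defuzzified reciprocal matrix; (4) row-mean IFNs are reduced to local
priorities with an entropy-based weighting; (5) local priorities compose
multiplicatively down the hierarchy into global weights.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ifs import IFN, TOL, LinguisticScale, ifwa, to_standard_fuzzy

__all__ = [
    "ExpertProfile",
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyReport",
    "SAATY_RANDOM_INDEX",
    "expert_weights",
    "aggregate_judgments",
    "reciprocal_matrix",
    "consistency_ratio",
    "eigenvector_weights",
    "row_ifn",
    "entropy_weights",
    "global_weights",
    "weigh_cluster",
]

log = logging.getLogger(__name__)

#: Saaty's random consistency indices by matrix order.
SAATY_RANDOM_INDEX: dict[int, float] = {
    3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49,
}


@dataclass(frozen=True)
class ExpertProfile:
    """A panel member identified by label with a knowledge-degree IFN."""

    id: str
    importance: IFN


@dataclass
class JudgmentMatrix:
    """A square matrix of IFN judgments from one expert over one cluster."""

    elements: list[str]
    cells: list[list[IFN]]
    expert_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n < 2:
            raise ValueError("a judgment matrix needs at least 2 elements")
        if len(self.cells) != n or any(len(row) != n for row in self.cells):
            raise ValueError("judgment matrix must be square over its elements")

    @property
    def n(self) -> int:
        return len(self.elements)

    def mu_array(self) -> np.ndarray:
        return np.array([[c.mu for c in row] for row in self.cells])

    def nu_array(self) -> np.ndarray:
        return np.array([[c.nu for c in row] for row in self.cells])

    @classmethod
    def from_labels(cls, elements: Sequence[str], labels: Sequence[Sequence[str]],
                    scale: LinguisticScale, expert_id: str = "") -> "JudgmentMatrix":
        cells = [[scale[lab] for lab in row] for row in labels]
        return cls(list(elements), cells, expert_id)


@dataclass
class WeightVector:
    """Local and (optionally) global priorities over decision elements."""

    elements: list[str]
    local: dict[str, float]
    global_: dict[str, float] | None = None
    parent: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        loc = np.array([self.local[e] for e in self.elements])
        if (loc < -1e-9).any():
            raise ValueError("local weights must be nonnegative")
        if self.global_ is None:
            # a bare local vector spans one cluster and must be normalized;
            # when globals are present the locals are per-cluster and the
            # globals carry the sum-to-one invariant instead
            if abs(loc.sum() - 1.0) > 1e-6:
                raise ValueError(f"local weights must sum to 1, got {loc.sum():.8g}")

    def global_array(self) -> np.ndarray:
        if self.global_ is None:
            raise ValueError("no global weights on this vector")
        return np.array([self.global_[e] for e in self.elements])

    def local_array(self) -> np.ndarray:
        return np.array([self.local[e] for e in self.elements])


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of a consistency check on an aggregated judgment matrix."""

    cr: float
    lambda_max: float
    n: int
    threshold: float = 0.10

    @property
    def consistent(self) -> bool:
        return self.cr < self.threshold


def expert_weights(panel: Sequence[ExpertProfile]) -> np.ndarray:
    """Relative priority of each panel member from their knowledge IFN.

    The raw score of expert *k* with importance ``(mu_k, nu_k, pi_k)`` is
    ``mu_k + pi_k * mu_k / (mu_k + nu_k)``: full membership plus the share
    of the hesitancy attributable to membership.  Scores are normalized to
    sum to one.  An expert with ``mu = nu = 0`` is rejected (the score is
    undefined).
    """
    if len(panel) == 0:
        raise ValueError("panel must be nonempty")
    scores = []
    for p in panel:
        mu, nu, pi = p.importance.as_tuple()
        if mu + nu <= TOL:
            raise ValueError(f"expert {p.id!r}: weight undefined for mu = nu = 0")
        scores.append(mu + pi * mu / (mu + nu))
    s = np.array(scores)
    return s / s.sum()


def aggregate_judgments(matrices: Sequence[JudgmentMatrix],
                        weights: Sequence[float]) -> JudgmentMatrix:
    """Pool per-expert judgment matrices cell-wise with the IFWA operator."""
    if len(matrices) == 0:
        raise ValueError("need at least one judgment matrix")
    if len(matrices) != len(weights):
        raise ValueError("one weight per expert matrix is required")
    ref = matrices[0].elements
    for m in matrices[1:]:
        if m.elements != ref:
            raise ValueError(
                f"element order mismatch between experts: {m.elements} vs {ref}"
            )
    n = len(ref)
    cells = [
        [ifwa([m.cells[i][j] for m in matrices], weights) for j in range(n)]
        for i in range(n)
    ]
    return JudgmentMatrix(list(ref), cells, expert_id="aggregated")


def reciprocal_matrix(matrix: JudgmentMatrix) -> np.ndarray:
    """Crisp Saaty-type reciprocal matrix from an aggregated IFN matrix.

    Each upper-triangle cell is defuzzified with the phi = 0.5 operator,
    the diagonal is forced to 1, and the lower triangle is the reciprocal
    of the upper — the positive reciprocal form the eigenvalue-based
    consistency test requires.
    """
    n = matrix.n
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = to_standard_fuzzy(matrix.cells[i][j])
            c = max(c, 1e-12)  # guard against a degenerate zero membership
            A[i, j] = c
            A[j, i] = 1.0 / c
    return A


def _principal_eigenvalue(A: np.ndarray) -> float:
    ev = np.linalg.eigvals(A)
    return float(ev.real.max())


def consistency_ratio(matrix: JudgmentMatrix,
                      ri_table: Mapping[int, float] | None = None,
                      threshold: float = 0.10) -> ConsistencyReport:
    """Saaty consistency ratio of an aggregated IFN judgment matrix.

    ``CR = ((lambda_max - n) / (n - 1)) / RI(n)`` where ``lambda_max`` is
    the principal eigenvalue of the defuzzified reciprocal matrix.  A matrix
    is acceptable when ``CR < 0.10``; an inconsistent matrix triggers a
    warning (judgments should be revised, never silently repaired).  For
    ``n <= 2`` the ratio is defined as 0.
    """
    n = matrix.n
    if n <= 2:
        return ConsistencyReport(0.0, float(n), n, threshold)
    ri = dict(SAATY_RANDOM_INDEX)
    if ri_table:
        ri.update(ri_table)
    if n not in ri:
        raise ValueError(
            f"no random index for n = {n}; supply an extended ri_table"
        )
    lam = _principal_eigenvalue(reciprocal_matrix(matrix))
    cr = max(0.0, (lam - n) / (n - 1)) / ri[n]
    report = ConsistencyReport(cr, lam, n, threshold)
    if not report.consistent:
        warnings.warn(
            f"judgment matrix over {matrix.elements} is inconsistent "
            f"(CR = {cr:.3f} >= {threshold}); the experts should revise "
            "their judgments",
            stacklevel=2,
        )
    return report


def eigenvector_weights(matrix: JudgmentMatrix) -> WeightVector:
    """Classical AHP priorities: principal eigenvector of the reciprocal matrix.

    Offered alongside :func:`entropy_weights` as the standard eigenvalue
    route; it recovers an underlying priority vector exactly when the
    judgments are perfectly consistent.
    """
    A = reciprocal_matrix(matrix)
    ev, vec = np.linalg.eig(A)
    k = int(np.argmax(ev.real))
    w = np.abs(vec[:, k].real)
    w = w / w.sum()
    return WeightVector(list(matrix.elements), dict(zip(matrix.elements, w)))


def row_ifn(matrix: JudgmentMatrix) -> list[IFN]:
    """Per-element row IFN: arithmetic mean of mu and of nu across the row."""
    out = []
    for row in matrix.cells:
        mu = float(np.mean([c.mu for c in row]))
        nu = float(np.mean([c.nu for c in row]))
        out.append(IFN(mu, nu))
    return out


def _xlogx(x: float) -> float:
    """x * ln x with the continuity convention 0 * ln 0 = 0."""
    return 0.0 if x <= 0.0 else x * math.log(x)


def entropy_weights(row_ifns: Sequence[IFN],
                    elements: Sequence[str] | None = None) -> WeightVector:
    """Entropy-based local priorities from per-element row IFNs.

    The intuitionistic fuzzy entropy of element *i* is::

        e_i = -(1/ln 2) * [mu ln mu + nu ln nu - (1-pi) ln(1-pi) - pi ln 2]

    (terms with a zero argument contribute 0).  Priorities are
    ``w_i = (1 - e_i) / (n - sum_j e_j)``, normalized to sum to one.
    """
    n = len(row_ifns)
    if n < 2:
        raise ValueError("entropy weighting needs at least 2 elements")
    if elements is None:
        elements = [f"E{i + 1}" for i in range(n)]
    ent = np.array(
        [
            -(1.0 / math.log(2))
            * (_xlogx(x.mu) + _xlogx(x.nu) - _xlogx(1.0 - x.pi) - x.pi * math.log(2))
            for x in row_ifns
        ]
    )
    denom = n - ent.sum()
    if abs(denom) < 1e-12:
        raise ValueError("entropy weights undefined: sum of entropies equals n")
    w = (1.0 - ent) / denom
    w = w / w.sum()
    return WeightVector(list(elements), dict(zip(elements, (float(v) for v in w))))


def global_weights(parent: WeightVector,
                   children: Mapping[str, WeightVector]) -> WeightVector:
    """Compose local sub-criterion weights with their parent criterion weights.

    The global weight of a sub-criterion is its local weight times the
    weight of its parent criterion; across a complete hierarchy the global
    weights sum to one.
    """
    for crit in children:
        if crit not in parent.local:
            raise ValueError(f"orphan sub-criteria: no parent weight for {crit!r}")
    elements: list[str] = []
    local: dict[str, float] = {}
    glob: dict[str, float] = {}
    parent_of: dict[str, str] = {}
    for crit in parent.elements:
        if crit not in children:
            continue
        child = children[crit]
        for e in child.elements:
            elements.append(e)
            local[e] = child.local[e]
            glob[e] = child.local[e] * parent.local[crit]
            parent_of[e] = crit
    total = sum(glob.values())
    covered = sum(parent.local[c] for c in children)
    if abs(total - covered) > 1e-6:
        raise ValueError("global weights do not compose: check child vectors")
    return WeightVector(elements, local, glob, parent_of)


def weigh_cluster(matrices: Sequence[JudgmentMatrix], panel_weights: Sequence[float],
                  threshold: float = 0.10) -> tuple[WeightVector, ConsistencyReport]:
    """Full per-cluster chain: aggregate, check consistency, extract priorities."""
    agg = aggregate_judgments(matrices, panel_weights)
    report = consistency_ratio(agg, threshold=threshold)
    wv = entropy_weights(row_ifn(agg), agg.elements)
    return wv, report


def weigh_hierarchy(panel: Sequence[ExpertProfile],
                    clusters: Mapping[str, Mapping[str, JudgmentMatrix]],
                    criteria_cluster: str = "criteria",
                    threshold: float = 0.10,
                    ) -> tuple[WeightVector, dict[str, ConsistencyReport]]:
    """Two-level weighting: criteria cluster plus one cluster per criterion.

    ``clusters`` maps a cluster id to per-expert judgment matrices; the
    cluster named ``criteria_cluster`` compares the criteria themselves and
    every other cluster id must match one criterion element.  Returns the
    global weight vector over all sub-criteria and the consistency report
    of every aggregated matrix.
    """
    if criteria_cluster not in clusters:
        raise ValueError(f"no {criteria_cluster!r} cluster among {sorted(clusters)}")
    w = expert_weights(panel)

    def in_panel_order(per_expert: Mapping[str, JudgmentMatrix]) -> list[JudgmentMatrix]:
        missing = [p.id for p in panel if p.id not in per_expert]
        if missing:
            raise ValueError(f"missing judgment matrices for experts {missing}")
        return [per_expert[p.id] for p in panel]

    reports: dict[str, ConsistencyReport] = {}
    parent, reports[criteria_cluster] = weigh_cluster(
        in_panel_order(clusters[criteria_cluster]), w, threshold
    )
    children: dict[str, WeightVector] = {}
    for cid, per_expert in clusters.items():
        if cid == criteria_cluster:
            continue
        children[cid], reports[cid] = weigh_cluster(in_panel_order(per_expert), w, threshold)
    return global_weights(parent, children), reports
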