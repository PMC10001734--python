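"""Intuitionistic-fuzzy DEMATEL: cause-effect analysis of a decision network.

Per-expert influence judgments on the intuitionistic linguistic scale are
defuzzified to crisp direct-relation matrices, averaged across the panel,
normalized, and propagated through the total-influence matrix
``T = N (I - N)^-1``.  Row sums ``D`` (influence dispatched) and column
sums ``R`` (influence received) classify each element as a *dispatcher*
(cause, ``D - R > 0``) or *receiver* (effect); links stronger than the mean
total influence are deemed significant and exported as a digraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ifs import IFN, DEMATEL_INFLUENCE, LinguisticScale, defuzzify_crisp, to_standard_fuzzy

__all__ = [
    "InfluenceMatrixSet",
    "InfluenceResult",
    "defuzzify_influence",
    "aggregate_direct_relation",
    "convergence_index",
    "normalize_direct_relation",
    "total_influence",
    "prominence_relation",
    "significant_links",
    "run_chain",
]

log = logging.getLogger(__name__)


@dataclass
class InfluenceMatrixSet:
    """Per-expert grids of IFN influence judgments over one element cluster."""

    elements: list[str]
    per_expert: list[list[list[IFN]]]
    expert_ids: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not self.per_expert:
            raise ValueError("need at least one expert grid")
        for g in self.per_expert:
            if len(g) != n or any(len(row) != n for row in g):
                raise ValueError("all influence grids must be square and conformant")


@dataclass
class InfluenceResult:
    """Prominence/relation scores and the significant-link digraph."""

    elements: list[str]
    D: np.ndarray
    R: np.ndarray
    theta: float
    links: list[tuple[str, str, float]]

    @property
    def prominence(self) -> np.ndarray:
        return self.D + self.R

    @property
    def relation(self) -> np.ndarray:
        return self.D - self.R

    @property
    def role(self) -> list[str]:
        # strict rule: D - R exactly 0 classifies as receiver
        return ["dispatcher" if d > 0 else "receiver" for d in self.relation]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": self.elements,
                "D": self.D,
                "R": self.R,
                "prominence": self.prominence,
                "relation": self.relation,
                "role": self.role,
            }
        )

    def to_network(self) -> nx.DiGraph:
        """Significant links as a directed graph (edge attribute ``weight``)."""
        g = nx.DiGraph(theta=self.theta)
        g.add_nodes_from(self.elements)
        for src, dst, w in self.links:
            g.add_edge(src, dst, weight=w)
        return g


def defuzzify_influence(grid: Sequence[Sequence[IFN]],
                        scale: LinguisticScale = DEMATEL_INFLUENCE) -> np.ndarray:
    """Crisp direct-relation matrix from an IFN influence grid.

    Each cell passes through the two-stage chain (phi = 0.5 collapse, then
    the linear triangular mapping on the scale's support); the diagonal is
    forced to zero — an element exerts no direct influence on itself.
    """
    n = len(grid)
    Z = np.zeros((n, n))
    for i, row in enumerate(grid):
        for j, cell in enumerate(row):
            if i == j:
                continue
            Z[i, j] = defuzzify_crisp(to_standard_fuzzy(cell), scale)
    return Z


def aggregate_direct_relation(matrices: Sequence[np.ndarray] | InfluenceMatrixSet,
                              scale: LinguisticScale = DEMATEL_INFLUENCE) -> np.ndarray:
    """Unweighted cell-wise mean of the experts' crisp direct-relation matrices.

    Accepts either already-crisp matrices or an :class:`InfluenceMatrixSet`
    of IFN grids (defuzzified first).  The panel mean is deliberately
    unweighted even when experts carry importance weights in the weighting
    stage; the influence stage treats the panel symmetrically.
    """
    if isinstance(matrices, InfluenceMatrixSet):
        crisp = [defuzzify_influence(g, scale) for g in matrices.per_expert]
    else:
        crisp = [np.asarray(m, dtype=float) for m in matrices]
    if len(crisp) == 0:
        raise ValueError("need at least one expert matrix")
    shape = crisp[0].shape
    if any(m.shape != shape for m in crisp):
        raise ValueError("expert matrices are not conformant")
    return np.mean(crisp, axis=0)


def convergence_index(agg_n: np.ndarray, agg_n_minus_1: np.ndarray) -> float:
    """Mean absolute relative change between successive aggregation steps.

    ``(1 / (n (n-1))) * sum_ij |g_ij^p - g_ij^(p-1)| / g_ij^p`` over
    off-diagonal cells; the panel is judged internally consistent when the
    index is <= 0.05.  Cells where the reference ``g_ij^p`` is zero are
    skipped with a logged warning (the diagonal, always zero, is excluded
    by construction).
    """
    A = np.asarray(agg_n, dtype=float)
    B = np.asarray(agg_n_minus_1, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and conformant")
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    if not A[off].any():
        raise ValueError("all-zero reference matrix: convergence index undefined")
    zero_ref = off & (A == 0)
    if zero_ref.any():
        log.warning("convergence index: skipping %d cells with zero reference", int(zero_ref.sum()))
    use = off & (A != 0)
    total = float(np.sum(np.abs(A[use] - B[use]) / A[use]))
    return total / (n * (n - 1))


def normalize_direct_relation(Z: np.ndarray) -> np.ndarray:
    """Scale the aggregated matrix by the largest row or column sum.

    ``N = Z / s`` with ``s = max(max_i sum_j z_ij, max_j sum_i z_ij)``;
    every row and column sum of ``N`` is then at most 1.
    """
    Z = np.asarray(Z, dtype=float)
    if (Z < 0).any():
        raise ValueError("direct-relation matrix must be nonnegative")
    s = max(Z.sum(axis=1).max(), Z.sum(axis=0).max())
    if s == 0:
        raise ValueError("all-zero direct-relation matrix cannot be normalized")
    return Z / s


def total_influence(N: np.ndarray) -> np.ndarray:
    """Total-influence matrix ``T = N (I - N)^-1``.

    Sums the geometric series of direct and indirect influence; requires
    the spectral radius of ``N`` to be strictly below 1, otherwise the
    series diverges and the computation is refused.
    """
    N = np.asarray(N, dtype=float)
    n = N.shape[0]
    radius = float(np.abs(np.linalg.eigvals(N)).max())
    if radius >= 1.0:
        raise np.linalg.LinAlgError(
            f"total influence diverges: spectral radius {radius:.4f} >= 1"
        )
    # T = N (I - N)^-1 via a dense solve on the transposed system
    T = np.linalg.solve((np.eye(n) - N).T, N.T).T
    return T


def significant_links(T: np.ndarray,
                      elements: Sequence[str] | None = None
                      ) -> tuple[float, list[tuple[str, str, float]]]:
    """Threshold and directed edges of the impact-digraph map.

    The threshold is the mean of all total-influence entries,
    ``theta = sum_ij t_ij / n^2``; an ordered pair (i, j) forms an edge
    exactly when ``t_ij > theta`` (strictly).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if elements is None:
        elements = [f"E{i + 1}" for i in range(n)]
    theta = float(T.sum()) / (n * n)
    links = [
        (elements[i], elements[j], float(T[i, j]))
        for i in range(n)
        for j in range(n)
        if T[i, j] > theta
    ]
    return theta, links


def prominence_relation(T: np.ndarray,
                        elements: Sequence[str] | None = None) -> InfluenceResult:
    """Dispatched/received influence, roles, and significant links from ``T``."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if elements is None:
        elements = [f"E{i + 1}" for i in range(n)]
    D = T.sum(axis=1)
    R = T.sum(axis=0)
    theta, links = significant_links(T, elements)
    return InfluenceResult(list(elements), D, R, theta, links)


def run_chain(Z: np.ndarray, elements: Sequence[str] | None = None) -> InfluenceResult:
    """Aggregated direct-relation matrix -> normalized -> total influence -> scores."""
    return prominence_relation(total_influence(normalize_direct_relation(Z)), elements)


def analyze_influence(mset: InfluenceMatrixSet,
                      scale: LinguisticScale = DEMATEL_INFLUENCE,
                      ) -> tuple[InfluenceResult, float | None]:
    """Full cluster analysis from per-expert IFN grids.

    Defuzzifies each expert's grid, aggregates sequentially in panel order,
    and returns the influence result together with the convergence index of
    the final aggregation step (the full-panel mean against the mean
    without the last expert).  With a single expert the index is undefined
    and ``None`` is returned with a warning.
    """
    crisp = [defuzzify_influence(g, scale) for g in mset.per_expert]
    Z = aggregate_direct_relation(crisp)
    if len(crisp) >= 2:
        conv = convergence_index(Z, np.mean(crisp[:-1], axis=0))
    else:
        log.warning("single-expert panel: convergence index undefined, skipped")
        conv = None
    return run_chain(Z, mset.elements), conv
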