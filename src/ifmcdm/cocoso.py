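"""Combined compromise solution (CoCoSo) ranking of alternatives.

Blends three aggregation strategies over a weighted, min-max normalized
decision matrix: the additive comparability ``S_i = sum_j w_j r_ij``
(simple additive weighting), the power comparability
``P_i = sum_j r_ij^w_j`` (multiplicative exponential weighting), and three
appraisal scores combining them.  The final compromise index

    M_i = (M_ia M_ib M_ic)^(1/3) + (M_ia + M_ib + M_ic) / 3

ranks the alternatives; here it plays the role of an overall performance
index for the units being compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix",
    "CoCoSoResult",
    "normalize_matrix",
    "comparability",
    "appraisal_scores",
    "final_index",
    "weakness_report",
    "rank_alternatives",
    "cocoso",
]

VALID_DIRECTIONS = {"benefit", "cost"}


@dataclass
class DecisionMatrix:
    """Alternatives x sub-criteria KPI measurements with directions and weights.

    ``directions[j]`` is ``"benefit"`` (larger is better) or ``"cost"``
    (smaller is better) for sub-criterion *j*; ``weights`` are the global
    priorities of the sub-criteria and must sum to one.
    """

    alternatives: list[str]
    subcriteria: list[str]
    values: np.ndarray
    directions: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        m, n = len(self.alternatives), len(self.subcriteria)
        if self.values.shape != (m, n):
            raise ValueError(f"values must be {m}x{n}, got {self.values.shape}")
        if len(self.directions) != n:
            raise ValueError("every sub-criterion needs a direction")
        bad = sorted(set(self.directions) - VALID_DIRECTIONS)
        if bad:
            raise ValueError(f"unknown directions {bad}; use 'benefit' or 'cost'")
        if self.weights.shape != (n,):
            raise ValueError("one weight per sub-criterion is required")
        if (self.weights < -1e-9).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum():.8g}")


@dataclass
class CoCoSoResult:
    """Per-alternative comparability, appraisal scores, final index, and ranks."""

    alternatives: list[str]
    S: np.ndarray
    P: np.ndarray
    Ma: np.ndarray
    Mb: np.ndarray
    Mc: np.ndarray
    M: np.ndarray
    rank: list[int]
    lam: float
    weak_subcriteria: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alternative": self.alternatives,
                "S": self.S,
                "P": self.P,
                "Ma": self.Ma,
                "Mb": self.Mb,
                "Mc": self.Mc,
                "M": self.M,
                "rank": self.rank,
            }
        )

    def ranking(self) -> list[str]:
        """Alternative ids from best (rank 1) to worst."""
        order = sorted(range(len(self.alternatives)), key=lambda i: self.rank[i])
        return [self.alternatives[i] for i in order]


def normalize_matrix(M: DecisionMatrix) -> np.ndarray:
    """Min-max normalization by direction.

    Benefit columns map ``(x - min) / (max - min)``, cost columns
    ``(max - x) / (max - min)``.  A constant column (max = min) carries no
    discriminating information and maps to 1 for every alternative — all
    tied at best — so a fully tied indicator still contributes its weight
    to the power comparability.
    """
    X = M.values
    r = np.empty_like(X)
    for j, direction in enumerate(M.directions):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            r[:, j] = 1.0
        elif direction == "benefit":
            r[:, j] = (col - lo) / (hi - lo)
        else:
            r[:, j] = (hi - col) / (hi - lo)
    return r


def comparability(r: np.ndarray, weights: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Weighted (S) and power-weighted (P) comparability per alternative.

    ``S_i = sum_j w_j r_ij`` lies in [0, 1]; ``P_i = sum_j r_ij^w_j`` with
    the convention ``0^w = 0`` for ``w > 0`` is bounded by the number of
    sub-criteria.
    """
    r = np.asarray(r, dtype=float)
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    S = r @ w
    with np.errstate(divide="ignore"):
        powers = np.where((r == 0) & (w > 0), 0.0, r ** w)
    P = powers.sum(axis=1)
    return S, P


def appraisal_scores(S: np.ndarray, P: np.ndarray,
                     lam: float = 0.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three CoCoSo appraisal scores.

    ``Ma = (P + S) / sum(P + S)`` (mean-relative), ``Mb = S/min S + P/min P``
    (relative to the worst), and
    ``Mc = (lam S + (1-lam) P) / (lam max S + (1-lam) max P)`` (compromise
    relative to the best, ``lam`` in [0, 1], default 0.5).  ``Mb`` is
    undefined when ``min S`` or ``min P`` is zero — that happens when one
    alternative is worst on every non-constant sub-criterion; drop it or
    adjust the cutoffs before ranking.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    if len(S) < 2:
        raise ValueError("at least two alternatives are required")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if S.min() <= 0 or P.min() <= 0:
        raise ValueError(
            "Mb undefined: an alternative has zero comparability (worst on all "
            "non-constant sub-criteria); remove it or revisit the decision matrix"
        )
    Ma = (P + S) / (P + S).sum()
    Mb = S / S.min() + P / P.min()
    Mc = (lam * S + (1 - lam) * P) / (lam * S.max() + (1 - lam) * P.max())
    return Ma, Mb, Mc


def final_index(Ma: np.ndarray, Mb: np.ndarray, Mc: np.ndarray) -> np.ndarray:
    """Compromise index: geometric mean plus arithmetic mean of the scores."""
    Ma, Mb, Mc = (np.asarray(x, dtype=float) for x in (Ma, Mb, Mc))
    if (Ma <= 0).any() or (Mb <= 0).any() or (Mc <= 0).any():
        raise ValueError("appraisal scores must be positive")
    return np.cbrt(Ma * Mb * Mc) + (Ma + Mb + Mc) / 3.0


def rank_alternatives(M: np.ndarray, alternatives: Sequence[str]) -> list[int]:
    """1-based ranks, descending by index, ties broken by alternative id."""
    order = sorted(range(len(alternatives)), key=lambda i: (-M[i], alternatives[i]))
    rank = [0] * len(alternatives)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    return rank


def weakness_report(M: DecisionMatrix, r: np.ndarray | None = None,
                    cutoff: float = 0.1) -> dict[str, list[str]]:
    """Sub-criteria on which each alternative performs at or near the worst.

    Flags, per alternative, the non-constant sub-criteria with normalized
    value <= ``cutoff`` (default 0.1), sorted by weight descending — the
    natural intervention points.  Constant columns are never flagged.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [0, 1)")
    if r is None:
        r = normalize_matrix(M)
    varying = M.values.max(axis=0) != M.values.min(axis=0)
    report: dict[str, list[str]] = {}
    for i, alt in enumerate(M.alternatives):
        weak = [j for j in range(len(M.subcriteria)) if varying[j] and r[i, j] <= cutoff]
        weak.sort(key=lambda j: -M.weights[j])
        report[alt] = [M.subcriteria[j] for j in weak]
    return report


def cocoso(M: DecisionMatrix, lam: float = 0.5, weakness_cutoff: float = 0.1) -> CoCoSoResult:
    """Full CoCoSo chain: normalize, compare, appraise, rank, flag weaknesses."""
    r = normalize_matrix(M)
    S, P = comparability(r, M.weights)
    Ma, Mb, Mc = appraisal_scores(S, P, lam)
    Mi = final_index(Ma, Mb, Mc)
    rank = rank_alternatives(Mi, M.alternatives)
    weak = weakness_report(M, r, weakness_cutoff)
    return CoCoSoResult(list(M.alternatives), S, P, Ma, Mb, Mc, Mi, rank, lam, weak)
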