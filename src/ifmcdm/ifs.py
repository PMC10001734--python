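"""Intuitionistic fuzzy number algebra and linguistic evaluation scales.

An intuitionistic fuzzy number (IFN) extends an ordinary fuzzy membership
degree ``mu`` with an explicit non-membership degree ``nu``; the residual
``pi = 1 - mu - nu`` is the *hesitancy* of the judge.  Expert judgments on a
linguistic scale (e.g. "high influence") map to IFNs, several experts'
judgments are pooled with the intuitionistic fuzzy weighted average (IFWA),
and a two-stage defuzzification chain — the ``C_phi`` operator at
``phi = 0.5`` followed by a linear triangular-number mapping — turns IFNs
back into crisp scores when a downstream method needs real numbers.

This module is the shared substrate of the AHP-style weighting stage
(:mod:`ifmcdm.ahp`) and the DEMATEL influence stage (:mod:`ifmcdm.dematel`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IFN",
    "LinguisticScale",
    "make_ifn",
    "to_standard_fuzzy",
    "defuzzify_crisp",
    "ifwa",
    "get_scale",
    "load_scale",
    "BUILTIN_SCALES",
]

#: Absolute tolerance for IFN validity checks.
TOL = 1e-9


@dataclass(frozen=True)
class IFN:
    """An intuitionistic fuzzy number (membership, non-membership).

    The hesitancy degree ``pi`` is always recomputed as ``1 - mu - nu`` and
    never stored independently, so the three degrees sum to one by
    construction.

    Raises
    ------
    ValueError
        If ``mu`` or ``nu`` lies outside [0, 1] or ``mu + nu > 1`` beyond a
        tolerance of ``1e-9``.
    """

    mu: float
    nu: float

    def __post_init__(self) -> None:
        if not (-TOL <= self.mu <= 1 + TOL) or not (-TOL <= self.nu <= 1 + TOL):
            raise ValueError(f"membership degrees must lie in [0, 1]: ({self.mu}, {self.nu})")
        if self.mu + self.nu > 1 + TOL:
            raise ValueError(
                f"invalid intuitionistic pair: mu + nu = {self.mu + self.nu:.6g} > 1"
            )

    @property
    def pi(self) -> float:
        """Hesitancy degree ``1 - mu - nu``, clamped to [0, 1]."""
        return min(1.0, max(0.0, 1.0 - self.mu - self.nu))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.nu, self.pi)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IFN(mu={self.mu:.4g}, nu={self.nu:.4g}, pi={self.pi:.4g})"


def make_ifn(mu: float, nu: float) -> IFN:
    """Build a validated IFN from membership and non-membership degrees."""
    return IFN(float(mu), float(nu))


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered linguistic evaluation scale whose labels map to IFNs.

    Parameters
    ----------
    name:
        Scale identifier, e.g. ``"dematel_influence"``.
    entries:
        Ordered mapping from label to IFN.
    crisp_support:
        Pair ``(l, m)`` giving the support of the triangular fuzzy number
        used when defuzzifying memberships elicited on this scale; the crisp
        value of a membership ``c`` is ``l + c * (m - l)``.  A third
        parameter ``u`` of the triangular number may be supplied but is not
        used by the linear mapping.
    """

    name: str
    entries: Mapping[str, IFN]
    crisp_support: tuple[float, float]
    u: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        l, m = self.crisp_support
        if not l < m:
            raise ValueError(f"crisp support requires l < m, got ({l}, {m})")
        if len(self.entries) == 0:
            raise ValueError("a linguistic scale needs at least one entry")

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def __getitem__(self, label: str) -> IFN:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(
                f"unknown label {label!r} for scale {self.name!r}; "
                f"expected one of {self.labels}"
            ) from None

    def crisp(self, label: str) -> float:
        """Crisp score of a label via the full defuzzification chain."""
        return defuzzify_crisp(to_standard_fuzzy(self[label]), self)


def to_standard_fuzzy(x: IFN) -> float:
    """Collapse an IFN to a classical fuzzy membership value.

    Applies the ``C_phi`` operator at ``phi = 0.5`` — the value minimising
    the Euclidean separation between the IFN and its classical image —
    splitting the hesitancy equally between membership and non-membership::

        mu(x) = (1 + mu - nu) / 2

    The result is guaranteed to lie in [0, 1].
    """
    return min(1.0, max(0.0, 0.5 * (1.0 + x.mu - x.nu)))


def defuzzify_crisp(membership: float, scale: LinguisticScale | tuple[float, float]) -> float:
    """Map a fuzzy membership to a crisp value on a scale's triangular support.

    Implements the linear mapping ``x = l + membership * (m - l)`` where
    ``(l, m)`` is the scale's crisp support.  With the influence scale's
    support ``(0, 4)`` this is simply ``4 * membership``.
    """
    if not (-TOL <= membership <= 1 + TOL):
        raise ValueError(f"membership must lie in [0, 1], got {membership}")
    l, m = scale.crisp_support if isinstance(scale, LinguisticScale) else scale
    return l + membership * (m - l)


def ifwa(values: Sequence[IFN], weights: Sequence[float]) -> IFN:
    """Intuitionistic fuzzy weighted average of several IFNs.

    For values ``(mu_k, nu_k)`` and nonnegative weights ``w_k`` summing to
    one::

        mu = 1 - prod (1 - mu_k)^w_k
        nu =     prod (nu_k)^w_k

    Products are evaluated in log space for numerical stability; the
    convention ``0^w = 0`` for ``w > 0`` applies, so a single certain
    judgment (``nu_k = 0``) with positive weight zeroes the aggregated
    non-membership.  The output always satisfies the IFN invariants.
    """
    if len(values) != len(weights):
        raise ValueError("values and weights must have the same length")
    if len(values) == 0:
        raise ValueError("ifwa requires at least one value")
    w = np.asarray(weights, dtype=float)
    if (w < -TOL).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum():.12g}")

    def weighted_product(xs: np.ndarray) -> float:
        # prod xs^w with the 0^w = 0 convention for w > 0
        active = w > 0
        if (xs[active] <= 0).any():
            return 0.0
        return float(np.exp(np.sum(w[active] * np.log(xs[active]))))

    one_minus_mu = np.array([1.0 - v.mu for v in values])
    nus = np.array([v.nu for v in values])
    p_mu = weighted_product(one_minus_mu)
    p_nu = weighted_product(nus)
    # rounding guard: p_nu <= p_mu must hold (nu_k <= 1 - mu_k cell-wise)
    p_nu = min(p_nu, p_mu)
    return IFN(min(1.0, max(0.0, 1.0 - p_mu)), min(1.0, max(0.0, p_nu)))


# ---------------------------------------------------------------------------
# Built-in scales
# ---------------------------------------------------------------------------

def _scale(name: str, pairs: Iterable[tuple[str, float, float]],
           support: tuple[float, float]) -> LinguisticScale:
    return LinguisticScale(name, {lab: IFN(mu, nu) for lab, mu, nu in pairs}, support)


#: Relevance scale for pairwise AHP-style comparisons.
AHP_RELEVANCE = _scale(
    "ahp_relevance",
    [
        ("much less relevant", 0.27, 0.33),
        ("less relevant", 0.27, 0.13),
        ("equally relevant", 0.02, 0.18),
        ("more relevant", 0.13, 0.27),
        ("much more relevant", 0.33, 0.27),
    ],
    (0.0, 1.0),
)

#: Influence scale for DEMATEL pairwise comparisons; crisp support (0, 4)
#: yields the canonical crisp scores {0.4, 1.5, 2.1, 3.1, 3.6}.
DEMATEL_INFLUENCE = _scale(
    "dematel_influence",
    [
        ("no influence", 0.10, 0.90),
        ("low influence", 0.35, 0.60),
        ("medium influence", 0.50, 0.45),
        ("high influence", 0.75, 0.20),
        ("very high influence", 0.90, 0.10),
    ],
    (0.0, 4.0),
)

#: Expert knowledge/importance scale used to weight panel members.
EXPERT_IMPORTANCE = _scale(
    "expert_importance",
    [
        ("very irrelevant", 0.10, 0.80),
        ("irrelevant", 0.25, 0.60),
        ("moderately relevant", 0.50, 0.40),
        ("relevant", 0.75, 0.20),
        ("very relevant", 0.90, 0.05),
    ],
    (0.0, 1.0),
)

BUILTIN_SCALES: dict[str, LinguisticScale] = {
    s.name: s for s in (AHP_RELEVANCE, DEMATEL_INFLUENCE, EXPERT_IMPORTANCE)
}


def get_scale(name: str) -> LinguisticScale:
    """Return a built-in scale by name."""
    try:
        return BUILTIN_SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; built-ins: {sorted(BUILTIN_SCALES)}"
        ) from None


def load_scale(path: str | Path) -> LinguisticScale:
    """Load a scale override from a JSON file.

    Expected shape::

        {"name": ..., "entries": [{"label": ..., "mu": ..., "nu": ...}, ...],
         "crisp_support": [l, m]}
    """
    raw = json.loads(Path(path).read_text())
    entries = {e["label"]: IFN(float(e["mu"]), float(e["nu"])) for e in raw["entries"]}
    support = tuple(float(v) for v in raw["crisp_support"])
    if len(support) == 3:  # an optional u parameter is accepted but unused
        return LinguisticScale(raw["name"], entries, support[:2], u=support[2])
    return LinguisticScale(raw["name"], entries, support)  # type: ignore[arg-type]
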