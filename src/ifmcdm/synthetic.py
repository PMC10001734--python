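"""Reproducible synthetic expert panels for end-to-end testing and simulation.

The generator emulates a panel of experts judging one cluster of decision
elements twice over: pairwise relevance comparisons for the weighting
stage, and pairwise influence judgments on the linguistic influence scale
for the cause-effect stage.

Relevance judgments are built from a hidden priority vector: each expert's
upper-triangle membership for the pair (i, j) is the priority ratio
``v_i / v_j`` perturbed by log-normal noise, re-encoded as an IFN with a
fixed hesitancy.  At zero noise every expert is perfectly consistent
(consistency ratio 0) and the classical eigenvector extraction recovers the
hidden vector exactly; at small noise the matrices stay below the 0.10
consistency threshold.  Influence grids draw labels independently per cell
from a configurable distribution over the influence scale, with the
diagonal fixed at the fully hesitant (0, 0) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ahp import ExpertProfile, JudgmentMatrix
from .dematel import InfluenceMatrixSet
from .ifs import AHP_RELEVANCE, DEMATEL_INFLUENCE, EXPERT_IMPORTANCE, IFN, LinguisticScale

__all__ = ["SyntheticPanelSpec", "SyntheticPanel", "generate_panel"]

#: Fixed hesitancy of generated relevance IFNs; memberships are clipped to
#: [pi/2, 1 - pi/2] so the IFN constraints hold.
_AHP_HESITANCY = 0.1

#: Default label distribution for influence judgments, weighted toward the
#: mid-to-high labels a panel of engaged domain experts typically uses.
_DEFAULT_INFLUENCE_PROBS = (0.10, 0.15, 0.25, 0.30, 0.20)

#: Default distribution of expert-importance labels: a senior panel of
#: mostly highly experienced members, mirroring a six-expert study panel
#: with five "very relevant" members and one "relevant" member.
_DEFAULT_IMPORTANCE_PROBS = {"very relevant": 5 / 6, "relevant": 1 / 6}


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Specification of a synthetic panel; identical spec + seed => identical output."""

    n_experts: int = 6
    n_elements: int = 4
    seed: int = 0
    noise: float = 0.1
    influence_scale: LinguisticScale = DEMATEL_INFLUENCE
    influence_probs: tuple[float, ...] = _DEFAULT_INFLUENCE_PROBS
    importance_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_IMPORTANCE_PROBS)
    )

    def __post_init__(self) -> None:
        if self.n_experts < 1 or self.n_elements < 2:
            raise ValueError("need at least 1 expert and 2 elements")
        if len(self.influence_probs) != len(self.influence_scale.entries):
            raise ValueError("one probability per influence label is required")


@dataclass
class SyntheticPanel:
    """Generated panel: profiles, judgment matrices, influence grids, ground truth."""

    profiles: list[ExpertProfile]
    ahp_matrices: list[JudgmentMatrix]
    influence: InfluenceMatrixSet
    priority: np.ndarray  # hidden priority vector the relevance judgments encode


def _relevance_ifn(membership: float) -> IFN:
    c = min(1.0 - _AHP_HESITANCY / 2, max(_AHP_HESITANCY / 2, membership))
    mu = c - _AHP_HESITANCY / 2
    nu = 1.0 - _AHP_HESITANCY - mu
    return IFN(mu, nu)


def generate_panel(spec: SyntheticPanelSpec) -> SyntheticPanel:
    """Draw a reproducible synthetic expert panel from a spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_elements
    elements = [f"E{i + 1}" for i in range(n)]

    # hidden log-priorities, increasing with bounded spread so that every
    # ratio v_i / v_j (i < j) stays inside the representable membership band
    gaps = rng.uniform(0.08, 0.35, size=n - 1)
    total = gaps.sum()
    if total > 2.9:
        gaps *= 2.9 / total
    logv = np.concatenate([[0.0], np.cumsum(gaps)])
    priority = np.exp(logv)
    priority = priority / priority.sum()

    # expert profiles
    labels = list(spec.importance_probs)
    probs = np.array([spec.importance_probs[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(labels, size=spec.n_experts, p=probs)
    profiles = [
        ExpertProfile(f"DM{k + 1}", EXPERT_IMPORTANCE[lab]) for k, lab in enumerate(drawn)
    ]

    equal = AHP_RELEVANCE["equally relevant"]
    ahp_matrices = []
    for k in range(spec.n_experts):
        cells = [[equal for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                eps = rng.normal(0.0, 1.0) if spec.noise > 0 else 0.0
                c = float(np.exp(logv[i] - logv[j] + spec.noise * eps))
                cells[i][j] = _relevance_ifn(c)
                # mirrored judgment for the lower triangle; the consistency
                # and priority computations use the upper triangle only
                cells[j][i] = _relevance_ifn(1.0 - c)
        ahp_matrices.append(JudgmentMatrix(elements, cells, expert_id=f"DM{k + 1}"))

    infl_labels = list(spec.influence_scale.entries)
    p = np.array(spec.influence_probs, dtype=float)
    p = p / p.sum()
    grids = []
    for k in range(spec.n_experts):
        grid = [[IFN(0.0, 0.0) for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i != j:
                    grid[i][j] = spec.influence_scale[str(rng.choice(infl_labels, p=p))]
        grids.append(grid)
    influence = InfluenceMatrixSet(elements, grids, [f"DM{k + 1}" for k in range(spec.n_experts)])

    return SyntheticPanel(profiles, ahp_matrices, influence, priority)
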