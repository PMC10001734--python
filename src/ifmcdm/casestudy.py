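"""Packaged case-study datasets and the KPI catalog.

The package ships the complete printed record of a three-hospital
emergency-department performance evaluation: the six-member expert panel,
an aggregated pairwise judgment matrix, per-expert and aggregated influence
matrices for the human-talent cluster, the 35-KPI decision matrix with
global weights, and the published reference outputs of every stage.  All
values are stored at the precision they were printed at (the aggregated
direct-relation matrix additionally at its exact sixth-based values, since
its cells are panel means of six crisp scores).

Each fixture carries a provenance string: ``"case study (printed)"`` for
values copied from the published record, ``"reconstructed"`` for curated
metadata the record leaves implicit (the benefit/cost direction vector,
the KPI formula kinds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .ahp import ExpertProfile, JudgmentMatrix
from .cocoso import DecisionMatrix
from .ifs import EXPERT_IMPORTANCE, IFN, DEMATEL_INFLUENCE

__all__ = ["KPIDefinition", "load_fixture", "fixture_names", "compute_kpi"]


def _path(name: str):
    return resources.files("ifmcdm.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class KPIDefinition:
    """How a sub-criterion's key performance indicator is computed."""

    subcriterion: str
    kind: str  # ratio-percent | binary | count | mean-interval
    metric: str
    units: str
    numerator: str | None = None
    denominator: str | None = None
    condition: str | None = None


def _load_expert_panel() -> list[ExpertProfile]:
    df = _read_csv("expert_panel.csv")
    return [
        ExpertProfile(r.expert_id, EXPERT_IMPORTANCE[r.importance_label])
        for r in df.itertuples()
    ]


def _load_equipment_judgments() -> JudgmentMatrix:
    df = _read_csv("equipment_aggregated_judgments.csv")
    elements = list(dict.fromkeys(df["row"]))
    cells = [[None] * len(elements) for _ in elements]
    idx = {e: i for i, e in enumerate(elements)}
    for r in df.itertuples():
        cells[idx[r.row]][idx[r.col]] = IFN(r.mu, r.nu)
    return JudgmentMatrix(elements, cells, expert_id="aggregated")


def _load_expert1_influence() -> tuple[list[str], list[list[IFN]]]:
    df = _read_csv("human_talent_expert1_influence.csv")
    elements = list(dict.fromkeys(df["row"]))
    idx = {e: i for i, e in enumerate(elements)}
    # the diagonal holds the fully hesitant pair (0, 0): no self-judgment
    grid = [[IFN(0.0, 0.0) for _ in elements] for _ in elements]
    for r in df.itertuples():
        grid[idx[r.row]][idx[r.col]] = DEMATEL_INFLUENCE[r.label]
    return elements, grid


def _load_direct_relation() -> tuple[list[str], np.ndarray]:
    df = _read_csv("human_talent_direct_relation.csv")
    elements = list(df["element"])
    return elements, df[elements].to_numpy(dtype=float)


def _load_decision_matrix() -> DecisionMatrix:
    df = _read_csv("decision_matrix.csv")
    alts = [c for c in df.columns if c not in ("subcriterion", "weight", "direction")]
    w = df["weight"].to_numpy(dtype=float)
    return DecisionMatrix(
        alternatives=alts,
        subcriteria=list(df["subcriterion"]),
        values=df[alts].to_numpy(dtype=float).T,
        directions=list(df["direction"]),
        weights=w / w.sum(),  # printed 3-d.p. weights sum to 1.004; renormalize
    )


def _load_kpi_catalog() -> dict[str, KPIDefinition]:
    raw = json.loads(_path("kpi_catalog.json").read_text())
    return {
        sc: KPIDefinition(
            subcriterion=sc,
            kind=d["kind"],
            metric=d["metric"],
            units=d["units"],
            numerator=d.get("numerator"),
            denominator=d.get("denominator"),
            condition=d.get("condition"),
        )
        for sc, d in raw.items()
    }


_LOADERS: dict[str, tuple[Any, str]] = {
    "expert_panel": (_load_expert_panel, "case study (printed)"),
    "equipment_aggregated_judgments": (_load_equipment_judgments, "case study (printed)"),
    "human_talent_expert1_influence": (_load_expert1_influence, "case study (printed)"),
    "human_talent_direct_relation": (
        _load_direct_relation,
        "case study (printed, de-rounded to exact panel means)",
    ),
    "decision_matrix": (
        _load_decision_matrix,
        "case study (printed values; direction vector reconstructed, configurable)",
    ),
    "kpi_catalog": (_load_kpi_catalog, "reconstructed"),
    "reference_equipment_row_ifns": (
        lambda: _read_csv("reference_equipment_row_ifns.csv"), "case study (printed)"),
    "reference_weights": (
        lambda: _read_csv("reference_weights.csv"), "case study (printed)"),
    "reference_consistency": (
        lambda: json.loads(_path("reference_consistency.json").read_text()),
        "case study (printed)"),
    "reference_human_talent_expert1_crisp": (
        lambda: _read_csv("reference_human_talent_expert1_crisp.csv"),
        "case study (printed)"),
    "reference_human_talent_influence": (
        lambda: _read_csv("reference_human_talent_influence.csv"),
        "case study (printed)"),
    "reference_thresholds": (
        lambda: json.loads(_path("reference_thresholds.json").read_text()),
        "case study (printed)"),
    "reference_cocoso": (
        lambda: _read_csv("reference_cocoso.csv"), "case study (printed)"),
}


def fixture_names() -> list[str]:
    return sorted(_LOADERS)


def load_fixture(name: str):
    """Load a registered case-study fixture by name."""
    try:
        loader, _ = _LOADERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}") from None
    return loader()


def fixture_provenance(name: str) -> str:
    return _LOADERS[name][1]


def compute_kpi(defn: KPIDefinition, raw: Mapping[str, float] | float | bool) -> float:
    """Evaluate a KPI from raw counts/measurements.

    ``ratio-percent`` expects ``{"numerator": ..., "denominator": ...}`` and
    returns a percentage; ``binary`` expects a truthy/falsy condition value;
    ``count`` a plain number; ``mean-interval`` ``{"total": ..., "count": ...}``.
    """
    if defn.kind == "ratio-percent":
        num, den = float(raw["numerator"]), float(raw["denominator"])
        if den <= 0:
            raise ZeroDivisionError(f"{defn.subcriterion}: ratio KPI needs a positive denominator")
        return 100.0 * num / den
    if defn.kind == "binary":
        return 1.0 if bool(raw) else 0.0
    if defn.kind == "count":
        return float(raw)
    if defn.kind == "mean-interval":
        total, count = float(raw["total"]), float(raw["count"])
        if count <= 0:
            raise ZeroDivisionError(f"{defn.subcriterion}: mean KPI needs a positive count")
        return total / count
    raise ValueError(f"unknown KPI kind {defn.kind!r}")
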