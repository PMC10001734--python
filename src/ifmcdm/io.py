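"""CSV/JSON input-output and run configuration.

CSV dialect: UTF-8, comma-separated, mandatory header row, "." decimal
separator.  Judgment files are long-form: one row per (expert, cluster,
element pair) with a linguistic label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .ahp import ConsistencyReport, ExpertProfile, JudgmentMatrix, WeightVector
from .cocoso import CoCoSoResult, DecisionMatrix
from .dematel import InfluenceMatrixSet, InfluenceResult
from .ifs import IFN, LinguisticScale


class InputError(ValueError):
    """Malformed or inconsistent input data (distinct CLI exit code)."""


@dataclass
class RunConfig:
    """Tunable thresholds and run options, round-trippable through JSON."""

    lam: float = 0.5
    weakness_cutoff: float = 0.1
    cr_threshold: float = 0.10
    convergence_threshold: float = 0.05
    seed: int = 0
    scale_file: str | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("cr_threshold", "convergence_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.lam <= 1.0:
            raise InputError("lambda must lie in [0, 1]")
        if not 0.0 <= self.weakness_cutoff < 1.0:
            raise InputError("weakness cutoff must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_panel_csv(path: str | Path, scale: LinguisticScale) -> list[ExpertProfile]:
    df = pd.read_csv(path)
    _require_columns(df, {"expert_id", "importance_label"}, path)
    panel = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            imp = scale[str(r.importance_label).strip()]
        except KeyError as e:
            raise InputError(f"{path}, row {i}: {e.args[0]}") from None
        panel.append(ExpertProfile(str(r.expert_id), imp))
    return panel


def read_judgments_csv(path: str | Path, scale: LinguisticScale,
                       diagonal: IFN | None = None
                       ) -> dict[str, dict[str, JudgmentMatrix]]:
    """Parse long-form judgments into per-cluster, per-expert matrices.

    Expected columns: ``expert_id, cluster_id, row_element, col_element,
    label`` — or ``mu, nu`` columns in place of ``label`` for judgments
    given directly as IFNs (as the synthetic generator exports them).
    Diagonal cells may be omitted; they are filled with ``diagonal``
    (default: the scale's "equally relevant" entry if present, else the
    fully hesitant (0, 0) pair).
    """
    df = pd.read_csv(path)
    base = {"expert_id", "cluster_id", "row_element", "col_element"}
    has_label = "label" in df.columns
    _require_columns(df, base | ({"label"} if has_label else {"mu", "nu"}), path)
    if diagonal is None:
        diagonal = scale.entries.get("equally relevant", IFN(0.0, 0.0))
    out: dict[str, dict[str, JudgmentMatrix]] = {}
    for (cluster, expert), sub in df.groupby(["cluster_id", "expert_id"], sort=False):
        elements = list(dict.fromkeys(list(sub["row_element"]) + list(sub["col_element"])))
        idx = {e: i for i, e in enumerate(elements)}
        cells: list[list[IFN | None]] = [
            [diagonal if i == j else None for j in range(len(elements))]
            for i in range(len(elements))
        ]
        for rowno, r in zip(sub.index, sub.itertuples()):
            if has_label:
                try:
                    ifn = scale[str(r.label).strip()]
                except KeyError as e:
                    raise InputError(f"{path}, row {rowno + 2}: {e.args[0]}") from None
            else:
                try:
                    ifn = IFN(float(r.mu), float(r.nu))
                except ValueError as e:
                    raise InputError(f"{path}, row {rowno + 2}: {e}") from None
            cells[idx[r.row_element]][idx[r.col_element]] = ifn
        for i in range(len(elements)):
            for j in range(len(elements)):
                if cells[i][j] is None:
                    raise InputError(
                        f"{path}: cluster {cluster!r}, expert {expert!r}: missing "
                        f"judgment for pair ({elements[i]}, {elements[j]})"
                    )
        out.setdefault(str(cluster), {})[str(expert)] = JudgmentMatrix(
            elements, cells, expert_id=str(expert)
        )
    return out


def judgments_to_influence_set(per_expert: Mapping[str, JudgmentMatrix]) -> InfluenceMatrixSet:
    experts = list(per_expert)
    ref = per_expert[experts[0]].elements
    for e in experts[1:]:
        if per_expert[e].elements != ref:
            raise InputError(f"expert {e!r}: element order differs from {experts[0]!r}")
    return InfluenceMatrixSet(list(ref), [per_expert[e].cells for e in experts], experts)


def read_decision_matrix_csv(path: str | Path,
                             weights: Mapping[str, float] | None = None) -> DecisionMatrix:
    """Decision matrix CSV: rows are sub-criteria, columns are alternatives,
    plus ``direction`` and (unless supplied separately) ``weight`` columns."""
    df = pd.read_csv(path)
    if "subcriterion" not in df.columns or "direction" not in df.columns:
        raise InputError(f"{path}: need 'subcriterion' and 'direction' columns")
    special = {"subcriterion", "weight", "direction"}
    alts = [c for c in df.columns if c not in special]
    if not alts:
        raise InputError(f"{path}: no alternative columns found")
    subs = list(df["subcriterion"])
    if weights is not None:
        missing = [s for s in subs if s not in weights]
        if missing:
            raise InputError(f"{path}: no weight supplied for sub-criteria {missing}")
        w = pd.Series([weights[s] for s in subs], dtype=float)
    elif "weight" in df.columns:
        w = df["weight"].astype(float)
    else:
        raise InputError(f"{path}: no 'weight' column and no weights supplied")
    w = w / w.sum()
    try:
        return DecisionMatrix(alts, subs, df[alts].to_numpy(dtype=float).T,
                              list(df["direction"]), w.to_numpy())
    except ValueError as e:
        raise InputError(f"{path}: {e}") from None


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def weights_to_csv(wv: WeightVector, path: str | Path,
                   reports: Mapping[str, ConsistencyReport] | None = None) -> None:
    rows = []
    for e in wv.elements:
        parent = wv.parent.get(e) if wv.parent else None
        cr = reports[parent].cr if reports and parent in reports else None
        rows.append(
            {
                "element": e,
                "local_weight": wv.local[e],
                "global_weight": wv.global_[e] if wv.global_ else wv.local[e],
                "parent": parent,
                "cr": cr,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def influence_to_csv(res: InfluenceResult, path: str | Path) -> None:
    res.to_frame().to_csv(path, index=False)


def edges_to_csv(res: InfluenceResult, path: str | Path) -> None:
    pd.DataFrame(
        [{"source": s, "target": t, "tij": w, "theta": res.theta} for s, t, w in res.links]
    ).to_csv(path, index=False)


def network_to_json(res: InfluenceResult, path: str | Path) -> None:
    data = nx.node_link_data(res.to_network(), edges="links")
    Path(path).write_text(json.dumps(data, indent=2))


def cocoso_to_csv(res: CoCoSoResult, path: str | Path) -> None:
    res.to_frame().to_csv(path, index=False)


def weakness_to_json(res: CoCoSoResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(res.weak_subcriteria, indent=2))


def write_manifest(out_dir: str | Path, inputs: Sequence[str | Path],
                   config: RunConfig) -> Path:
    """Machine-readable run manifest: input hashes, config, package version."""
    from . import __version__

    entries = {}
    for p in inputs:
        p = Path(p)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"inputs_sha256": entries, "config": asdict(config), "version": __version__}
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
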