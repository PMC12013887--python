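"""Chameleon-pair analysis pipeline.

A *chameleon sequence* is an identical 6-12-residue stretch that adopts a
helix in one protein and a beta strand in another.  For each member of a
chameleon pair the pipeline determines the FOD-M status of the structural
unit (RD, K) and of the chameleon fragment within it (RD(FR)), classifies
the pair by which side of the RD = 0.5 threshold its units fall on, builds
the (higher RD, lower RD) scatter, and measures the correlation with
iterative outlier pruning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import FodStatus, fragment_rd, unit_profiles, unit_status
from .scales import HydrophobicityScale, default_scale
from .structure import (
    EffectiveAtomModel,
    FragmentSpec,
    StructureError,
    effective_atoms,
    find_fragment,
    read_structure,
    select_unit,
)

logger = logging.getLogger(__name__)


@dataclass
class UnitAnalysis:
    """FOD-M status of one structural unit plus its chameleon fragment."""

    structure_id: str
    unit_status: FodStatus
    fragment: FragmentSpec
    fragment_status: FodStatus
    secondary_form: str = "other"  # helix / beta / other, metadata from the manifest


@dataclass
class PairRecord:
    """Two structural units sharing a chameleon sequence, plus the pair class.

    Sub-bases: A — both units RD < 0.5 (micelle-like); B — both RD > 0.5;
    C — mixed (one on each side of the threshold).
    """

    member_a: UnitAnalysis
    member_b: UnitAnalysis
    subbase: str = ""
    pair_id: str = ""

    def __post_init__(self) -> None:
        expected = classify_pair(self.member_a.unit_status.rd, self.member_b.unit_status.rd)
        if not self.subbase:
            self.subbase = expected
        elif self.subbase != expected:
            raise ValueError(
                f"subbase {self.subbase!r} inconsistent with unit RDs "
                f"({self.member_a.unit_status.rd:.3f}, {self.member_b.unit_status.rd:.3f})"
            )
        if not self.pair_id:
            self.pair_id = f"{self.member_a.structure_id}:{self.member_b.structure_id}"


@dataclass(frozen=True)
class ScatterPoint:
    """One pair as a point: x the higher RD of the pair, y the lower."""

    x: float
    y: float
    kind: str  # unit | fragment
    pair_id: str

    def __post_init__(self) -> None:
        if self.x < self.y:
            raise ValueError("scatter point must have x >= y")


class StageError(RuntimeError):
    """An analysis step failed; carries the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze_model(
    model: EffectiveAtomModel,
    fragment: str | FragmentSpec | None,
    structure_id: str = "",
    secondary_form: str = "other",
    **core_kwargs,
) -> UnitAnalysis:
    """Run the FOD-M analysis on an already-built effective-atom model.

    Computes T/O/R profiles and RD for the unit, fits K, locates the
    chameleon fragment (by sequence or explicit range; ``None`` takes the
    whole unit) and computes its renormalized RD(FR).
    """
    try:
        profiles = unit_profiles(model, **core_kwargs)
        status = unit_status(profiles)
    except (ValueError, StructureError) as exc:
        raise StageError("profiles", exc) from exc
    try:
        if fragment is None:
            spec = FragmentSpec(0, len(model), model.sequence)
        elif isinstance(fragment, FragmentSpec):
            spec = fragment
        else:
            spec = find_fragment(model, fragment)
    except (ValueError, StructureError) as exc:
        raise StageError("find_fragment", exc) from exc
    try:
        frag_status = fragment_rd(profiles.T, profiles.O, profiles.R, spec)
    except (ValueError, StructureError) as exc:
        raise StageError("fragment_rd", exc) from exc
    return UnitAnalysis(
        structure_id=structure_id or "unit",
        unit_status=status,
        fragment=spec,
        fragment_status=frag_status,
        secondary_form=secondary_form,
    )


def analyze_unit(
    path: str | Path,
    chain: str,
    fragment: str | FragmentSpec | None,
    ranges: list[tuple[int, int]] | str = "all",
    scale: HydrophobicityScale | None = None,
    structure_id: str = "",
    secondary_form: str = "other",
    format: str = "auto",
    **core_kwargs,
) -> UnitAnalysis:
    """Full per-protein procedure from a structure file.

    Stages: read structure → select the structural unit (chain, optional
    domain residue ranges) → reduce to effective atoms → fit the envelope and
    compute T/O/R → RD and K for the unit → locate the chameleon fragment →
    renormalized RD(FR).  Errors carry the failing stage name.
    """
    scale = scale or default_scale()
    try:
        structure = read_structure(path, format=format)
    except StructureError as exc:
        raise StageError("read_structure", exc) from exc
    try:
        residues = select_unit(structure, chain, ranges)
    except StructureError as exc:
        raise StageError("select_unit", exc) from exc
    try:
        model = effective_atoms(residues, scale, chain_id=chain)
    except (StructureError, ValueError) as exc:
        raise StageError("effective_atoms", exc) from exc
    return analyze_model(
        model,
        fragment,
        structure_id=structure_id or f"{Path(path).stem}:{chain}",
        secondary_form=secondary_form,
        **core_kwargs,
    )


def classify_pair(rd_a: float, rd_b: float, threshold: float = 0.5) -> str:
    """Sub-base label: A if both RD < threshold, B if both > threshold, else C.

    Values exactly at the threshold are neither "<" nor ">", so a pair with
    one RD at the threshold falls into class C.
    """
    for v in (rd_a, rd_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"RD value {v} outside [0, 1]")
    if rd_a < threshold and rd_b < threshold:
        return "A"
    if rd_a > threshold and rd_b > threshold:
        return "B"
    return "C"


def pair_scatter(records: list[PairRecord], kind: str = "fragment") -> list[ScatterPoint]:
    """One point per pair: x = the higher RD of the pair, y = the lower.

    ``kind`` selects unit RDs or fragment RD(FR)s.
    """
    if not records:
        raise ValueError("no pair records")
    if kind not in ("unit", "fragment"):
        raise ValueError(f"kind must be 'unit' or 'fragment', got {kind!r}")
    points = []
    for rec in records:
        if kind == "unit":
            a, b = rec.member_a.unit_status.rd, rec.member_b.unit_status.rd
        else:
            a, b = rec.member_a.fragment_status.rd, rec.member_b.fragment_status.rd
        points.append(ScatterPoint(x=max(a, b), y=min(a, b), kind=kind, pair_id=rec.pair_id))
    return points


def pearson(points: list[ScatterPoint]) -> float:
    """Product-moment correlation of the (x, y) scatter."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis")
    return float(stats.pearsonr(x, y).statistic)


def prune_outliers(
    points: list[ScatterPoint],
    r_threshold: float = 0.7,
) -> tuple[list[ScatterPoint], list[ScatterPoint], list[float], bool]:
    """Iteratively remove the worst OLS outlier until r exceeds the threshold.

    At each step an ordinary least squares line y ~ x is fitted and the point
    with the largest absolute residual removed; iteration stops when the
    correlation exceeds ``r_threshold`` or only 3 points would remain.
    Returns (kept, removed in order, r history, threshold_reached); the r
    history has one entry per state, so its length is removals + 1.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points to prune")
    kept = list(points)
    removed: list[ScatterPoint] = []
    r_history = [pearson(kept)]
    while r_history[-1] <= r_threshold and len(kept) > 3:
        x = np.array([p.x for p in kept])
        y = np.array([p.y for p in kept])
        slope, intercept = np.polyfit(x, y, 1)
        residuals = np.abs(y - (slope * x + intercept))
        worst = int(np.argmax(residuals))
        removed.append(kept.pop(worst))
        r_history.append(pearson(kept))
    return kept, removed, r_history, r_history[-1] > r_threshold


def report(records: list[PairRecord]) -> pd.DataFrame:
    """Tabular pair summary: ids, unit RD/K per side, RD(FR) per side, sequence, class."""
    rows = []
    for rec in records:
        a, b = rec.member_a, rec.member_b
        rows.append(
            {
                "pair_id": rec.pair_id,
                "id_a": a.structure_id,
                "rd_a": a.unit_status.rd,
                "k_a": a.unit_status.k,
                "rd_fr_a": a.fragment_status.rd,
                "sequence": a.fragment.sequence or b.fragment.sequence,
                "rd_fr_b": b.fragment_status.rd,
                "rd_b": b.unit_status.rd,
                "k_b": b.unit_status.k,
                "id_b": b.structure_id,
                "subbase": rec.subbase,
            }
        )
    columns = [
        "pair_id", "id_a", "rd_a", "k_a", "rd_fr_a", "sequence",
        "rd_fr_b", "rd_b", "k_b", "id_b", "subbase",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(records: list[PairRecord], out_dir: str | Path) -> None:
    """Write `pairs.tsv` (3-decimal presentation) and `pairs.json` (full precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = report(records)
    pretty = df.copy()
    for col in ("rd_a", "k_a", "rd_fr_a", "rd_fr_b", "rd_b", "k_b"):
        pretty[col] = pretty[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.3f}")
    pretty.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    (out_dir / "pairs.json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, default=float) + "\n"
    )


def write_scatter(points: list[ScatterPoint], path: str | Path) -> None:
    """Write `x, y, kind, pair_id` rows."""
    df = pd.DataFrame([asdict(p) for p in points], columns=["x", "y", "kind", "pair_id"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_pruning(
    removed: list[ScatterPoint],
    r_history: list[float],
    reached: bool,
    path: str | Path,
) -> None:
    payload = {
        "removed": [asdict(p) for p in removed],
        "r_history": r_history,
        "threshold_reached": reached,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
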