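"""Structure input: reading PDB/mmCIF files, selecting structural units,
reducing residues to effective atoms and locating fragments by sequence.

A *structural unit* is the chain or domain over which the Gaussian envelope
and the hydrophobicity profiles are computed; its residues are each reduced
to a single *effective atom*, the unweighted mean position of the residue's
heavy atoms, carrying the residue's intrinsic hydrophobicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .scales import HydrophobicityScale

logger = logging.getLogger(__name__)

_THREE_TO_ONE_EXTRA = {"MSE": "M"}  # selenomethionine treated as methionine


class StructureError(ValueError):
    """Raised for unreadable files, empty selections and malformed fragments."""


@dataclass(frozen=True)
class ResidueRef:
    """Identity of one residue in file (author) numbering."""

    chain_id: str
    author_number: int
    insertion_code: str
    aa: str

    def __post_init__(self) -> None:
        if len(self.aa) != 1:
            raise ValueError(f"aa must be a one-letter code, got {self.aa!r}")


@dataclass
class EffectiveAtomModel:
    """Ordered residues, one effective point and one Hir value each.

    This is the sole geometric input to every profile computation.
    """

    residues: list[ResidueRef]
    coords: np.ndarray  # (N, 3), Angstrom
    hydrophobicity: np.ndarray  # (N,), dimensionless in [0, 1]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hydrophobicity = np.asarray(self.hydrophobicity, dtype=float)
        n = len(self.residues)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.hydrophobicity.shape != (n,):
            raise ValueError(f"hydrophobicity shape {self.hydrophobicity.shape} != ({n},)")
        if n < 2:
            raise ValueError("a model needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate in model")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def to_tsv(self, path: str | Path) -> None:
        """Write `chain, resnum, icode, aa, x, y, z, H` rows."""
        lines = ["chain\tresnum\ticode\taa\tx\ty\tz\tH"]
        for ref, xyz, h in zip(self.residues, self.coords, self.hydrophobicity):
            lines.append(
                f"{ref.chain_id}\t{ref.author_number}\t{ref.insertion_code}\t{ref.aa}\t"
                f"{xyz[0]:.17g}\t{xyz[1]:.17g}\t{xyz[2]:.17g}\t{h:.17g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EffectiveAtomModel":
        residues, coords, hydro = [], [], []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            chain, resnum, icode, aa, x, y, z, h = line.split("\t")
            residues.append(ResidueRef(chain, int(resnum), icode, aa))
            coords.append([float(x), float(y), float(z)])
            hydro.append(float(h))
        return cls(residues, np.array(coords), np.array(hydro))


@dataclass(frozen=True)
class FragmentSpec:
    """Half-open 0-based index range [start, end) into a unit's residue list."""

    start: int
    end: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment range [{self.start}, {self.end})")
        if self.sequence and self.end - self.start != len(self.sequence):
            raise ValueError("fragment range length disagrees with its sequence")

    def __len__(self) -> int:
        return self.end - self.start


def read_structure(path: str | Path, format: str = "auto") -> gemmi.Structure:
    """Read a PDB or mmCIF file into a cleaned single-model structure.

    Waters and ligands are removed, hydrogens stripped, and only the first
    conformer of any alternate-location group kept.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise StructureError(f"unknown format {format!r} (use pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps the first conformer
    st.remove_hydrogens()
    st.remove_ligands_and_waters()
    st.remove_empty_chains()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise StructureError(f"no residues left after cleanup in {path}")
    return st


def _one_letter(resname: str) -> str:
    if resname in _THREE_TO_ONE_EXTRA:
        return _THREE_TO_ONE_EXTRA[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() and info.is_standard() else "X"


def _merge_intervals(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    for lo, hi in ranges:
        if lo > hi:
            raise StructureError(f"malformed interval {lo}-{hi} (lo > hi)")
    ordered = sorted(ranges)
    merged = [ordered[0]]
    overlap = False
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            overlap = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    if overlap:
        logger.warning("overlapping residue intervals merged: %s -> %s", ranges, merged)
    return merged


def select_unit(
    structure: gemmi.Structure,
    chain_id: str,
    ranges: list[tuple[int, int]] | str = "all",
) -> list[gemmi.Residue]:
    """Residues of one chain restricted to a union of inclusive author-number intervals.

    ``ranges="all"`` takes the whole chain.  Domain boundaries (e.g. from a
    CATH assignment) are supplied by the caller in author numbering.
    """
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise StructureError(f"chain {chain_id!r} not found (available: {available})")
    if ranges == "all":
        selected = list(chain)
    else:
        merged = _merge_intervals(list(ranges))
        selected = [
            res for res in chain
            if any(lo <= res.seqid.num <= hi for lo, hi in merged)
        ]
    if not selected:
        raise StructureError(f"no residues selected from chain {chain_id!r}")
    return selected


def effective_atoms(
    residues: list[gemmi.Residue],
    scale: HydrophobicityScale,
    chain_id: str = "",
    unknown_policy: str = "skip",
) -> EffectiveAtomModel:
    """Reduce residues to effective atoms under an intrinsic hydrophobicity scale.

    The effective point is the unweighted mean of heavy-atom positions;
    hydrogens, when present, are ignored so that results do not depend on
    whether the file includes them.  Residues whose one-letter code is not in
    the scale are skipped with a warning (``unknown_policy="skip"``, default)
    or raise (``"fail"``).
    """
    if unknown_policy not in ("skip", "fail"):
        raise ValueError(f"unknown_policy must be 'skip' or 'fail', got {unknown_policy!r}")
    refs, coords, hydro = [], [], []
    for res in residues:
        heavy = [a for a in res if a.element.name != "H" and a.element.name != "D"]
        if not heavy:
            logger.warning("residue %s %s has no heavy atoms; dropped", res.name, res.seqid)
            continue
        aa = _one_letter(res.name)
        if aa == "X" or aa not in scale:
            if unknown_policy == "fail":
                raise StructureError(f"residue {res.name} ({res.seqid}) not in scale")
            logger.warning("residue %s (%s) not in scale; skipped", res.name, res.seqid)
            continue
        pos = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in heavy])
        refs.append(
            ResidueRef(
                chain_id or (res.subchain or ""),
                res.seqid.num,
                res.seqid.icode.strip(),
                aa,
            )
        )
        coords.append(pos.mean(axis=0))
        hydro.append(scale[aa])
    if len(refs) < 2:
        raise StructureError("fewer than 2 usable residues after reduction")
    return EffectiveAtomModel(refs, np.array(coords), np.array(hydro))


def find_fragment(model: EffectiveAtomModel, sequence: str) -> FragmentSpec:
    """Locate a unique contiguous sequence match within the unit.

    Used to place a chameleon section (6-12 residues in that use) inside its
    structural unit.  Ambiguous matches raise, listing all positions, so the
    caller can disambiguate with an explicit residue range.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise StructureError("fragment sequence must have length >= 3")
    if not all(c.isalpha() for c in sequence):
        raise StructureError(f"invalid fragment sequence {sequence!r}")
    unit_seq = model.sequence
    positions = []
    start = unit_seq.find(sequence)
    while start != -1:
        positions.append(start)
        start = unit_seq.find(sequence, start + 1)
    if not positions:
        raise StructureError(f"fragment {sequence!r} not found in unit sequence")
    if len(positions) > 1:
        raise StructureError(
            f"fragment {sequence!r} matches at multiple positions {positions}; "
            "disambiguate with an explicit residue range"
        )
    return FragmentSpec(positions[0], positions[0] + len(sequence), sequence)
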