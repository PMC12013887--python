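"""Intrinsic amino-acid hydrophobicity scales.

The model weights pairwise hydrophobic interactions by the intrinsic
hydrophobicity ``Hir`` of each residue; any scale normalized to [0, 1] can be
used.  The shipped default is the Kyte-Doolittle hydropathy index min-max
rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle hydropathy index (raw values).
_KD_RAW = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """A one-letter-code -> Hir table, with Hir in [0, 1] for every standard residue."""

    table: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self.table))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {''.join(missing)}")
        values = [self.table[aa] for aa in STANDARD_AA]
        if min(values) < 0 or max(values) > 1:
            raise ValueError(f"scale {self.name!r} has values outside [0, 1]")

    def __getitem__(self, aa: str) -> float:
        return self.table[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.table

    def nearest_residue(self, h: float) -> str:
        """Standard residue whose Hir is closest to ``h`` (ties: alphabetical)."""
        return min(STANDARD_AA, key=lambda aa: (abs(self.table[aa] - h), aa))


def _minmax(raw: dict[str, float]) -> dict[str, float]:
    lo, hi = min(raw.values()), max(raw.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in raw.items()}


def default_scale() -> HydrophobicityScale:
    """Kyte-Doolittle hydropathy, min-max normalized to [0, 1]."""
    return HydrophobicityScale(_minmax(_KD_RAW), name="kyte-doolittle-normalized")


def load_scale(path: str | Path, name: str | None = None, normalize: bool = False) -> HydrophobicityScale:
    """Load a two-column ``AA<TAB>value`` table (header line optional).

    With ``normalize=True`` the values are min-max rescaled to [0, 1]; otherwise
    they must already lie in [0, 1].
    """
    path = Path(path)
    table: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'AA value', got {line!r}")
        aa, value = parts
        aa = aa.upper()
        if aa in ("AA", "RESIDUE") or (len(aa) > 1 and lineno == 1):
            continue  # header
        if len(aa) != 1:
            raise ValueError(f"{path}:{lineno}: residue code must be one letter, got {aa!r}")
        table[aa] = float(value)
    if normalize:
        table = _minmax(table)
    return HydrophobicityScale(table, name=name or path.stem)
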