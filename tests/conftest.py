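"""Shared fixtures: hand-written PDB text and small synthetic models."""

from __future__ import annotations

import numpy as np
import pytest

from fodm import GeneratorConfig, default_scale, make_cloud


def pdb_atom(serial, name, resname, chain, resseq, x, y, z,
             altloc=" ", icode=" ", occ=1.0, record="ATOM  ", element=None):
    """One fixed-width PDB coordinate record."""
    element = element or name.strip()[0]
    return (
        f"{record}{serial:>5} {name:<4}{altloc}{resname:>3} {chain}{resseq:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


def minimal_pdb_text() -> str:
    """Two-residue chain A (ALA 1, GLY 2) with an altloc pair and a water."""
    lines = [
        pdb_atom(1, " N  ", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom(2, " CA ", "ALA", "A", 1, 2.0, 0.0, 0.0),
        pdb_atom(3, " C  ", "ALA", "A", 1, 2.0, 2.0, 0.0),
        pdb_atom(4, " O  ", "ALA", "A", 1, 2.0, 2.0, 2.0),
        pdb_atom(5, " N  ", "GLY", "A", 2, 5.0, 0.0, 0.0),
        pdb_atom(6, " CA ", "GLY", "A", 2, 5.0, 2.0, 0.0, altloc="A"),
        pdb_atom(7, " CA ", "GLY", "A", 2, 9.0, 2.0, 0.0, altloc="B", occ=0.4),
        pdb_atom(8, " C  ", "GLY", "A", 2, 5.0, 2.0, 2.0),
        "TER",
        pdb_atom(9, " O  ", "HOH", "A", 101, 0.0, 0.0, 9.0, record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def chain_pdb_text(sequence: str, chain: str = "A", spacing: float = 3.8) -> str:
    """A straight-line poly-residue chain with N/CA/C/O atoms, one residue per letter."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        x = i * spacing
        # helical wobble keeps the effective atoms non-collinear
        wy, wz = 2.0 * np.sin(0.7 * i), 2.0 * np.cos(0.7 * i)
        for name, dy, dz in ((" N  ", 0.0, 0.0), (" CA ", 1.0, 0.0),
                             (" C  ", 1.0, 1.0), (" O  ", 0.0, 1.0)):
            lines.append(pdb_atom(serial, name, three[aa], chain, i + 1, x, wy + dy, wz + dz))
            serial += 1
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(minimal_pdb_text())
    return path


@pytest.fixture
def scale():
    return default_scale()


@pytest.fixture
def micelle_model():
    return make_cloud(GeneratorConfig(seed=7, geometry="micelle"))


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


def random_distribution(rng, n: int) -> np.ndarray:
    p = rng.random(n) + 1e-3
    return p / p.sum()
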