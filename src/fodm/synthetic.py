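"""Synthetic test structures and profile fixtures.

Every stage of the package is testable offline: the generator builds
point-cloud "proteins" with a prescribed hydrophobicity geometry (a
micelle-like gradient, its inversion, or a featureless uniform assignment),
profile-level fixtures with a known environment parameter K, and synthetic
chameleon-pair populations with a chosen fragment-RD correlation.

The clouds are statistical stand-ins, not polymers: residues are placed
independently in a ball, with no chain connectivity or excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import m_profile, uniform_profile
from .pipeline import PairRecord, UnitAnalysis
from .core import FodStatus
from .scales import HydrophobicityScale, default_scale
from .structure import EffectiveAtomModel, FragmentSpec, ResidueRef

DEFAULT_N_RESIDUES = 150
DEFAULT_RADIUS = 15.0  # Angstrom; density comparable to a ~150-aa globule
DEFAULT_CONTRAST = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic point-cloud protein."""

    n_residues: int = DEFAULT_N_RESIDUES
    seed: int = 0
    geometry: str = "micelle"  # micelle | inverted | uniform
    radius: float = DEFAULT_RADIUS
    hydropathy_contrast: float = DEFAULT_CONTRAST

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.geometry not in ("micelle", "inverted", "uniform"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not 0.0 <= self.hydropathy_contrast <= 1.0:
            raise ValueError("hydropathy_contrast must be in [0, 1]")


def make_cloud(
    config: GeneratorConfig,
    scale: HydrophobicityScale | None = None,
) -> EffectiveAtomModel:
    """Generate a seeded point-cloud model with prescribed hydrophobicity geometry.

    Residues are placed uniformly in a ball of the configured radius.  With
    ``geometry="micelle"`` the assigned Hir decreases linearly with distance
    from the center (hydrophobic core, polar surface); ``"inverted"``
    reverses the gradient (polar core, hydrophobic surface, the membrane-like
    anti-pattern); ``"uniform"`` assigns a constant mid-scale Hir.  The
    contrast scales the gradient's amplitude around 0.5.  Sequence letters
    are the residues whose scale value is nearest the assigned Hir.
    """
    scale = scale or default_scale()
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    # uniform in a ball: direction ~ isotropic, radius ~ R * U^(1/3)
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = config.radius * rng.random(n) ** (1.0 / 3.0)
    coords = direction * r[:, None]

    rel = r / config.radius  # 0 at center, 1 at surface
    if config.geometry == "micelle":
        base = 1.0 - rel
    elif config.geometry == "inverted":
        base = rel
    else:
        base = np.full(n, 0.5)
    h = 0.5 + config.hydropathy_contrast * (base - 0.5)

    residues = []
    hir = np.empty(n)
    for i, target in enumerate(h):
        aa = scale.nearest_residue(float(target))
        residues.append(ResidueRef("S", i + 1, "", aa))
        hir[i] = scale[aa]
    return EffectiveAtomModel(residues, coords, hir)


def make_k_fixture(
    n: int,
    k_true: float,
    seed: int,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A (T, O) profile pair with a known environment parameter.

    T is a random normalized profile; O is the modified profile M(T, k_true)
    with optional multiplicative log-normal noise (scale ``noise_sd``), then
    renormalized.  Noise-free, the K estimator must recover ``k_true``.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    if k_true < 0:
        raise ValueError("k_true must be nonnegative")
    rng = np.random.default_rng(seed)
    T = rng.random(n) + 0.05  # bounded away from 0 so profiles stay well-conditioned
    T = T / T.sum()
    O = m_profile(T, k_true)
    if noise_sd > 0:
        O = O * np.exp(rng.normal(scale=noise_sd, size=n))
        O = O / O.sum()
    return T, O


def _status(rd_value: float, n: int = 100) -> FodStatus:
    # synthetic FodStatus with divergences consistent with the prescribed RD
    dkl_or = 1.0
    dkl_ot = rd_value * dkl_or / (1.0 - rd_value) if rd_value < 1.0 else 1e9
    return FodStatus(rd=dkl_ot / (dkl_ot + dkl_or), dkl_ot=dkl_ot, dkl_or=dkl_or, n_residues=n)


def make_pair_population(
    n_pairs: int,
    rho: float,
    seed: int,
) -> list[PairRecord]:
    """Synthetic class-C chameleon-pair population with correlated fragment RDs.

    The higher and lower fragment RD(FR) of each pair are drawn from a
    bivariate normal with correlation ``rho``, centered in disjoint bands
    (0.75 and 0.35, sd 0.08) and truncated to [0, 1], so the (higher, lower)
    scatter built from the records carries correlation rho.  Unit RDs are
    drawn so that each pair straddles the 0.5 threshold (one unit below, one
    above), forcing sub-base C membership.  Exercises the scatter,
    correlation and pruning steps end-to-end without structure files.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    mean = np.array([0.75, 0.35])
    cov = 0.08**2 * np.array([[1.0, rho], [rho, 1.0]])
    frag = rng.multivariate_normal(mean, cov, size=n_pairs)
    frag = np.clip(frag, 0.0, 1.0)
    low = rng.uniform(0.25, 0.499, size=n_pairs)
    high = rng.uniform(0.501, 0.75, size=n_pairs)

    records = []
    for i in range(n_pairs):
        spec = FragmentSpec(0, 7, "AAAAAAA")
        a = UnitAnalysis(
            structure_id=f"synA{i:03d}",
            unit_status=_status(low[i]),
            fragment=spec,
            fragment_status=_status(frag[i, 0]),
            secondary_form="beta",
        )
        b = UnitAnalysis(
            structure_id=f"synB{i:03d}",
            unit_status=_status(high[i]),
            fragment=spec,
            fragment_status=_status(frag[i, 1]),
            secondary_form="helix",
        )
        records.append(PairRecord(member_a=a, member_b=b, pair_id=f"pair{i:03d}"))
    return records
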