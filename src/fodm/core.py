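"""Core FOD-M computations: T/O/R/M profiles, the RD statistic and the
environment parameter K.

All profiles are per-residue probability distributions (nonnegative, sum 1)
over a structural unit:

* ``T`` — theoretical micelle-like profile: a 3D Gaussian envelope fitted to
  the unit, evaluated at each effective atom and normalized.
* ``O`` — observed profile: pairwise hydrophobic interactions through the
  Levitt polynomial with a 9 Å cutoff, normalized.
* ``R`` — uniform reference, 1/N per residue.
* ``M`` — environment-modified field ``T + K*(Tmax - T)``, normalized; ``K``
  interpolates from the aqueous field (K=0, M=T) to the fully inverted
  membrane-like field (K→inf, M ∝ Tmax - T).

``RD = DKL(O|T) / (DKL(O|T) + DKL(O|R))`` measures micelle-likeness:
RD < 0.5 means the observed distribution is closer to the centric-core ideal
than to the featureless uniform reference.  ``K`` is the argmin over K of
``DKL(O | M(T, K))`` and quantifies how non-aqueous an environment is needed
to explain the observed distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .structure import EffectiveAtomModel, FragmentSpec

logger = logging.getLogger(__name__)

EPS = 1e-12  # floor applied before any log or normalization of raw profiles
DEFAULT_CUTOFF = 9.0  # Angstrom, Levitt interaction cutoff
DEFAULT_SIGMA_DIVISOR = 3.0  # three-sigma rule: envelope spans the molecule


@dataclass(frozen=True)
class GaussianEnvelope:
    """3D Gaussian fitted to a structural unit.

    ``rotation`` has principal axes as rows: frame coordinates of a point p
    are ``rotation @ (p - center)``.  Sigmas are per-axis, in Å, ordered with
    the longest axis first.
    """

    center: np.ndarray  # (3,)
    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    sigmas: np.ndarray  # (3,) strictly positive

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be strictly positive")

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Express coordinates in the principal-axis frame."""
        return (np.asarray(coords, dtype=float) - self.center) @ self.rotation.T


@dataclass
class ProfileSet:
    """Aligned normalized T/O/R (and optionally M) distributions over a unit."""

    T: np.ndarray
    O: np.ndarray
    R: np.ndarray
    M: np.ndarray | None = None
    K_of_M: float | None = None

    def __post_init__(self) -> None:
        n = len(self.T)
        for name in ("T", "O", "R", "M"):
            p = getattr(self, name)
            if p is None:
                continue
            p = np.asarray(p, dtype=float)
            setattr(self, name, p)
            if len(p) != n:
                raise ValueError(f"profile {name} length {len(p)} != {n}")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile {name} is not a distribution")

    @property
    def n(self) -> int:
        return len(self.T)


@dataclass(frozen=True)
class FodStatus:
    """RD, K and the underlying divergences (bits) for a unit or fragment."""

    rd: float
    dkl_ot: float
    dkl_or: float
    n_residues: int
    k: float | None = None
    dkl_om_at_k: float | None = None

    def __post_init__(self) -> None:
        denom = self.dkl_ot + self.dkl_or
        if denom > 0 and abs(self.rd - self.dkl_ot / denom) > 1e-9:
            raise ValueError("rd inconsistent with its divergences")
        if self.k is not None and self.k < 0:
            raise ValueError("k must be nonnegative")


def fit_envelope(coords: np.ndarray, sigma_divisor: float = DEFAULT_SIGMA_DIVISOR) -> GaussianEnvelope:
    """Fit the Gaussian envelope to a point cloud.

    Center is the coordinate mean; axes are the principal components of the
    centered cloud (decreasing variance, right-handed); each sigma is the
    maximal absolute projection on its axis divided by ``sigma_divisor``, so
    that with the default divisor 3 the envelope spans the molecule under the
    three-sigma rule.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order].T  # rows = axes, longest first
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]  # keep the frame right-handed
    proj = centered @ axes.T
    extents = np.abs(proj).max(axis=0)
    for i, ext in enumerate(extents):
        if ext <= 0:
            raise ValueError(f"degenerate point cloud: zero extent on axis {i}")
    return GaussianEnvelope(center, axes, extents / sigma_divisor)


def theoretical_profile(model: EffectiveAtomModel, envelope: GaussianEnvelope) -> np.ndarray:
    """Micelle-like T profile: the envelope Gaussian at each effective atom, normalized."""
    frame = envelope.to_frame(model.coords)
    log_raw = -0.5 * np.sum((frame / envelope.sigmas) ** 2, axis=1)
    raw = np.exp(log_raw)
    return raw / raw.sum()


def levitt_weight(r: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Levitt's hydrophobic-contact weight: 1 at r=0, 0 at and beyond the cutoff."""
    x2 = (np.asarray(r, dtype=float) / cutoff) ** 2
    w = 1.0 - 0.5 * (7.0 * x2 - 9.0 * x2**2 + 5.0 * x2**3 - x2**4)
    return np.where(np.asarray(r) <= cutoff, w, 0.0)


def observed_profile(
    model: EffectiveAtomModel,
    cutoff_c: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> np.ndarray:
    """Observed O profile from pairwise hydrophobic interactions.

    Raw value of residue i is ``sum_j (Hir_i + Hir_j) * w(r_ij)`` over
    partners within the cutoff; ``include_self`` adds the j=i term
    (``2*Hir_i`` since w(0)=1), guarding against zero rows for isolated polar
    residues.  A tiny floor is added before normalization.
    """
    if cutoff_c <= 0:
        raise ValueError("cutoff must be positive")
    coords = model.coords
    h = model.hydrophobicity
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    w = levitt_weight(dist, cutoff_c)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    pair_h = h[:, None] + h[None, :]
    raw = (pair_h * w).sum(axis=1)
    if raw.sum() <= 0:
        raise ValueError(
            "all observed hydrophobicities are zero; enable include_self or use a nonzero scale"
        )
    raw = raw + EPS
    return raw / raw.sum()


def uniform_profile(n: int) -> np.ndarray:
    """Uniform reference R: 1/N per residue (no hydrophobic core)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.full(n, 1.0 / n)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum_i P_i log2(P_i/Q_i), in bits.

    Q is floored at 1e-12 and renormalized; terms with P_i = 0 contribute 0.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    Q = np.maximum(Q, EPS)
    Q = Q / Q.sum()
    mask = P > 0
    val = float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))
    return max(val, 0.0)  # clip float-error negatives; KL is nonnegative


def rd(O: np.ndarray, T: np.ndarray, R: np.ndarray) -> FodStatus:
    """Relative distance RD = DKL(O|T) / (DKL(O|T) + DKL(O|R)).

    RD < 0.5 is read as presence of a hydrophobic core.  The degenerate
    all-uniform case O == T == R (0/0) is defined as 0.5 with a warning.
    """
    dkl_ot = kl_divergence(O, T)
    dkl_or = kl_divergence(O, R)
    denom = dkl_ot + dkl_or
    if denom == 0.0:
        warnings.warn("O == T == R exactly; RD defined as 0.5 for this degenerate unit")
        return FodStatus(rd=0.5, dkl_ot=0.0, dkl_or=0.0, n_residues=len(O))
    return FodStatus(rd=dkl_ot / denom, dkl_ot=dkl_ot, dkl_or=dkl_or, n_residues=len(O))


def m_profile(T: np.ndarray, K: float) -> np.ndarray:
    """Environment-modified profile: normalize(T + K*(Tmax - T)).

    K=0 reproduces T; K→inf tends to the normalized complement (Tmax - T),
    the fully membrane-like field.  A constant T yields the uniform profile
    for any K.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    T = np.asarray(T, dtype=float)
    raw = T + K * (T.max() - T)
    total = raw.sum()
    if total <= 0:
        # K→inf numerically with constant T: fall back to uniform
        return uniform_profile(len(T))
    return raw / total


def estimate_k(
    O: np.ndarray,
    T: np.ndarray,
    k_max: float = 10.0,
    coarse_step: float = 0.01,
) -> tuple[float, float]:
    """Environment parameter K: argmin over K of DKL(O | M(T, K)).

    A coarse grid scan over [0, k_max] brackets the minimum; golden-section
    refinement (tolerance 1e-4) polishes it.  Ties break toward smaller K
    (the more aqueous explanation).  A minimum at k_max is returned with a
    boundary warning.
    """
    O = np.asarray(O, dtype=float)
    T = np.asarray(T, dtype=float)
    if O.shape != T.shape:
        raise ValueError("O and T must be aligned")

    def objective(k: float) -> float:
        return kl_divergence(O, m_profile(T, k))

    grid = np.arange(0.0, k_max + coarse_step / 2, coarse_step)
    values = np.array([objective(k) for k in grid])
    i = int(np.argmin(values))  # argmin takes the first minimum: smaller K wins ties
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        k_best, f_best = float(grid[i]), float(values[i])
    else:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        k_best, f_best = float(res.x), float(res.fun)
        if values[i] <= f_best:  # keep the grid point if refinement did not improve
            k_best, f_best = float(grid[i]), float(values[i])
    if k_best >= k_max - coarse_step:
        warnings.warn(
            f"K estimate {k_best:.4g} lies at the search boundary k_max={k_max}; "
            "the environment parameter may exceed the modeled range"
        )
    if k_best < 1e-6 and objective(0.0) <= f_best + 1e-15:
        k_best, f_best = 0.0, objective(0.0)
    return k_best, f_best


def fragment_rd(
    T: np.ndarray,
    O: np.ndarray,
    R: np.ndarray,
    fragment: FragmentSpec,
) -> FodStatus:
    """RD(FR): the RD statistic of a chain fragment.

    The unit-level profiles (with the Gaussian envelope fitted to the whole
    unit) are sliced on the fragment and each slice renormalized to sum 1
    before the divergences are taken, so RD(FR) measures the fragment's local
    contribution to the unit's hydrophobicity arrangement.
    """
    n = len(T)
    if not (0 <= fragment.start < fragment.end <= n):
        raise ValueError(f"fragment [{fragment.start}, {fragment.end}) outside unit of {n}")
    if len(fragment) < 2:
        raise ValueError("fragment must span at least 2 residues")
    sl = slice(fragment.start, fragment.end)

    def renorm(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)[sl]
        return p / p.sum()

    return rd(renorm(O), renorm(T), renorm(R))


def unit_profiles(
    model: EffectiveAtomModel,
    cutoff_c: float = DEFAULT_CUTOFF,
    include_self: bool = True,
    sigma_divisor: float = DEFAULT_SIGMA_DIVISOR,
    k_max: float | None = 10.0,
) -> ProfileSet:
    """T/O/R/M profiles of a structural unit, with K fitted to the observed profile.

    ``k_max=None`` skips the K fit (M and K_of_M left unset), for callers
    that only need RD.
    """
    envelope = fit_envelope(model.coords, sigma_divisor=sigma_divisor)
    T = theoretical_profile(model, envelope)
    O = observed_profile(model, cutoff_c=cutoff_c, include_self=include_self)
    R = uniform_profile(len(model))
    if k_max is None:
        return ProfileSet(T=T, O=O, R=R)
    k, _ = estimate_k(O, T, k_max=k_max)
    M = m_profile(T, k)
    return ProfileSet(T=T, O=O, R=R, M=M, K_of_M=k)


def unit_status(profiles: ProfileSet) -> FodStatus:
    """Unit-level FOD-M status (RD plus K) from a computed profile set."""
    status = rd(profiles.O, profiles.T, profiles.R)
    if profiles.K_of_M is not None:
        dkl_om = kl_divergence(profiles.O, profiles.M)
        status = FodStatus(
            rd=status.rd,
            dkl_ot=status.dkl_ot,
            dkl_or=status.dkl_or,
            n_residues=status.n_residues,
            k=profiles.K_of_M,
            dkl_om_at_k=dkl_om,
        )
    return status
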