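"""Profiles, divergences, RD and the environment parameter K.

Independent oracles used here: hand/pen evaluation of the Gaussian and KL
formulas, an explicit double-loop pairwise summation for the observed
profile, brute-force PCA on lattices for the envelope, and a dense K-grid
scan for the K estimator.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fodm import (
    EffectiveAtomModel,
    FragmentSpec,
    ResidueRef,
    estimate_k,
    fit_envelope,
    fragment_rd,
    kl_divergence,
    m_profile,
    observed_profile,
    rd,
    theoretical_profile,
    unit_profiles,
)
from fodm.core import levitt_weight, uniform_profile
from fodm.structure import EffectiveAtomModel

from conftest import random_distribution


def toy_model(coords, hydro):
    coords = np.asarray(coords, dtype=float)
    refs = [ResidueRef("A", i + 1, "", "A") for i in range(len(coords))]
    return EffectiveAtomModel(refs, coords, np.asarray(hydro, dtype=float))


# ---------------------------------------------------------------- envelope

class TestFitEnvelope:
    def test_cube_corners(self):
        corners = np.array([[sx * 3, sy * 3, sz * 3]
                            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float)
        env = fit_envelope(corners)
        np.testing.assert_allclose(env.center, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(env.sigmas, [1.0, 1.0, 1.0])  # extent 3 / divisor 3

    def test_box_lattice_matches_brute_force_pca(self):
        # 30 x 6 x 6 Angstrom box lattice: long axis first, sigmas ~ (5, 1, 1)
        xs, ys, zs = np.meshgrid(np.linspace(-15, 15, 11),
                                 np.linspace(-3, 3, 5),
                                 np.linspace(-3, 3, 5), indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        env = fit_envelope(pts)
        np.testing.assert_allclose(env.sigmas, [5.0, 1.0, 1.0], atol=1e-9)
        # brute-force PCA oracle: eigvecs of covariance, by decreasing eigval
        cov = np.cov(pts.T, bias=True)
        w, v = np.linalg.eigh(cov)
        axes = v[:, np.argsort(w)[::-1]].T
        for ax_ours, ax_pca in zip(env.rotation, axes):
            assert abs(abs(ax_ours @ ax_pca) - 1.0) < 1e-9  # same axis up to sign

    def test_rigid_motion_leaves_sigmas(self, rng):
        pts = rng.normal(size=(40, 3)) * [8, 3, 2]
        R = Rotation.random(random_state=4).as_matrix()
        moved = pts @ R.T + np.array([10.0, -5.0, 2.5])
        np.testing.assert_allclose(fit_envelope(pts).sigmas,
                                   fit_envelope(moved).sigmas, atol=1e-9)

    def test_degenerate_plane_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="axis"):
            fit_envelope(pts)

    def test_rotation_is_right_handed(self, rng):
        env = fit_envelope(rng.normal(size=(30, 3)) * [5, 2, 1])
        assert np.linalg.det(env.rotation) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- T profile

class TestTheoreticalProfile:
    def test_center_residue_has_max(self, rng):
        # symmetric cloud: envelope center is exactly the origin, where one
        # residue sits, so that residue takes the Gaussian peak (raw value 1)
        half = rng.normal(size=(10, 3)) * 5
        coords = np.vstack([[0.0, 0.0, 0.0], half, -half])
        model = toy_model(coords, np.full(len(coords), 0.5))
        T = theoretical_profile(model, fit_envelope(coords))
        assert np.argmax(T) == 0

    def test_symmetric_residues_equal(self):
        coords = np.array([[-4, 0, 0], [4, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 1], [0, 0, -1]], float)
        model = toy_model(coords, np.full(6, 0.5))
        T = theoretical_profile(model, fit_envelope(coords))
        assert T[0] == pytest.approx(T[1], abs=1e-12)
        assert T[2] == pytest.approx(T[3], abs=1e-12)

    def test_three_collinear_hand_values(self):
        # residues at axis coords (-s, 0, +s): raw = (e^-1/2, 1, e^-1/2),
        # so the middle value is 1 / (1 + 2 e^-1/2) ~ 0.4519
        s = 2.0
        coords = np.array([[-s, 0.1, 0.1], [0, 0.1, 0.1], [s, 0.1, 0.1]])
        model = toy_model(coords, np.full(3, 0.5))
        env_coords = np.array([[-3 * s, 0, 0], [3 * s, 0, 0],
                               [0, 3 * 0.5, 0], [0, -3 * 0.5, 0],
                               [0, 0, 3 * 0.5], [0, 0, -3 * 0.5]])
        env = fit_envelope(env_coords)  # sigma_x = s exactly
        # shift model into the envelope's own center/frame
        model.coords = model.coords - np.array([0.0, 0.1, 0.1])
        T = theoretical_profile(model, env)
        expected_mid = 1.0 / (1.0 + 2.0 * np.exp(-0.5))
        assert T[1] == pytest.approx(expected_mid, abs=1e-12)
        assert T[0] == pytest.approx(np.exp(-0.5) * expected_mid, abs=1e-12)


# ---------------------------------------------------------------- O profile

def brute_force_observed(coords, hydro, cutoff=9.0, include_self=True):
    """Independent double-loop implementation of the pairwise summation."""
    n = len(coords)
    raw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j and not include_self:
                continue
            r = np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j]))
            if r <= cutoff:
                x = r / cutoff
                w = 1 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)
                raw[i] += (hydro[i] + hydro[j]) * w
    raw = raw + 1e-12
    return raw / raw.sum()


class TestObservedProfile:
    def test_weight_vanishes_at_cutoff(self):
        assert levitt_weight(9.0) == pytest.approx(0.0, abs=1e-15)
        assert levitt_weight(0.0) == pytest.approx(1.0)
        assert levitt_weight(9.0001) == 0.0

    def test_pair_at_cutoff_boundary(self):
        model = toy_model([[0, 0, 0], [9.0, 0, 0]], [0.5, 0.5])
        O = observed_profile(model, cutoff_c=9.0)
        np.testing.assert_allclose(O, [0.5, 0.5], atol=1e-9)

    def test_identical_pair_symmetric(self):
        model = toy_model([[0, 0, 0], [4.0, 0, 0]], [0.3, 0.3])
        np.testing.assert_allclose(observed_profile(model), [0.5, 0.5], atol=1e-12)

    def test_three_on_line_matches_brute_force(self):
        coords = [[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]
        hydro = [1.0, 0.5, 0.0]
        model = toy_model(coords, hydro)
        np.testing.assert_allclose(observed_profile(model),
                                   brute_force_observed(coords, hydro), atol=1e-12)

    @pytest.mark.parametrize("include_self", [True, False])
    def test_random_cloud_matches_brute_force(self, rng, include_self):
        coords = rng.normal(size=(25, 3)) * 6
        hydro = rng.random(25)
        model = toy_model(coords, hydro)
        ours = observed_profile(model, include_self=include_self)
        oracle = brute_force_observed(coords, hydro, include_self=include_self)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_all_zero_without_self_term_raises(self):
        model = toy_model([[0, 0, 0], [50.0, 0, 0]], [0.4, 0.4])  # isolated residues
        with pytest.raises(ValueError, match="include_self"):
            observed_profile(model, include_self=False)


# ---------------------------------------------------------------- KL / RD

class TestKlDivergence:
    def test_identity_is_zero(self, rng):
        p = random_distribution(rng, 30)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_term_hand_value(self):
        # 0.5*log2(2) + 0.5*log2(2/3)
        expected = 0.5 + 0.5 * np.log2(2.0 / 3.0)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(expected, abs=1e-12)

    def test_zero_p_terms_contribute_nothing(self):
        assert kl_divergence([0.0, 1.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kl_divergence([0.5, 0.5], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(5, 60), st.integers(0, 2**31 - 1))
    def test_nonnegative_on_random_pairs(self, n, seed):
        rng = np.random.default_rng(seed)
        assert kl_divergence(random_distribution(rng, n), random_distribution(rng, n)) >= 0.0


class TestRd:
    def test_o_equals_t_gives_zero(self, rng):
        T = random_distribution(rng, 40)
        R = uniform_profile(40)
        assert rd(T, T, R).rd == pytest.approx(0.0, abs=1e-9)

    def test_o_equals_r_gives_one(self, rng):
        T = random_distribution(rng, 40)
        R = uniform_profile(40)
        assert rd(R, T, R).rd == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_all_uniform_is_half_with_warning(self):
        R = uniform_profile(10)
        with pytest.warns(UserWarning, match="degenerate"):
            assert rd(R, R, R).rd == 0.5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(5, 50), st.integers(0, 2**31 - 1))
    def test_rd_in_unit_interval(self, n, seed):
        rng = np.random.default_rng(seed)
        status = rd(random_distribution(rng, n), random_distribution(rng, n), uniform_profile(n))
        assert 0.0 <= status.rd <= 1.0
        assert status.rd == pytest.approx(status.dkl_ot / (status.dkl_ot + status.dkl_or), abs=1e-9)


# ---------------------------------------------------------------- M / K

class TestMProfile:
    def test_k_zero_is_t(self, rng):
        T = random_distribution(rng, 25)
        np.testing.assert_allclose(m_profile(T, 0.0), T, atol=1e-15)

    def test_large_k_limit_is_normalized_complement(self):
        T = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(m_profile(T, 1e12), [0.0, 0.4, 0.6], atol=1e-9)

    def test_interior_point_uniform(self):
        # T=(0.5,0.3,0.2), K=1: raw=(0.5,0.5,0.5) -> uniform
        np.testing.assert_allclose(m_profile(np.array([0.5, 0.3, 0.2]), 1.0),
                                   [1 / 3] * 3, atol=1e-12)

    def test_constant_t_gives_uniform(self):
        np.testing.assert_allclose(m_profile(np.full(4, 0.25), 2.0), np.full(4, 0.25))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(5, 30), st.integers(0, 2**31 - 1))
    def test_monotone_toward_complement_limit(self, n, seed):
        rng = np.random.default_rng(seed)
        T = random_distribution(rng, n)
        limit = m_profile(T, 1e12)
        ks = [0.0, 0.2, 0.5, 1.0, 3.0, 10.0]
        profiles = [m_profile(T, k) for k in ks]
        below_max = T < T.max()
        for a, b in zip(profiles, profiles[1:]):
            gap_a = np.abs(a[below_max] - limit[below_max])
            gap_b = np.abs(b[below_max] - limit[below_max])
            assert np.all(gap_b <= gap_a + 1e-12)


def fine_grid_k(O, T, k_max=10.0, step=1e-4):
    """Dense-grid oracle for the K estimate (vectorized over the grid)."""
    ks = np.arange(0.0, k_max + step / 2, step)
    d = T.max() - T
    raw = T[None, :] + ks[:, None] * d[None, :]
    M = raw / raw.sum(axis=1, keepdims=True)
    M = np.maximum(M, 1e-12)
    M = M / M.sum(axis=1, keepdims=True)
    mask = O > 0
    dkl = (O[mask] * np.log2(O[mask][None, :] / M[:, mask])).sum(axis=1)
    return ks[int(np.argmin(dkl))]


class TestEstimateK:
    def test_o_equals_t_gives_zero(self, rng):
        T = random_distribution(rng, 30)
        k, dkl = estimate_k(T, T)
        assert k == 0.0
        assert dkl == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k_true", [0.0, 0.3, 0.93, 3.0])
    def test_noise_free_recovery(self, k_true, rng):
        T = random_distribution(rng, 50)
        O = m_profile(T, k_true)
        k, _ = estimate_k(O, T)
        assert k == pytest.approx(k_true, abs=1e-3)

    def test_agrees_with_fine_grid_oracle(self, rng):
        for _ in range(20):
            T = random_distribution(rng, 40)
            O = m_profile(T, rng.uniform(0, 4)) * np.exp(rng.normal(scale=0.03, size=40))
            O = O / O.sum()
            k_ours, _ = estimate_k(O, T)
            k_oracle = fine_grid_k(O, T)
            assert k_ours == pytest.approx(k_oracle, abs=2e-4)

    def test_boundary_minimum_warns(self, rng):
        T = random_distribution(rng, 30)
        O = m_profile(T, 50.0)  # true K beyond k_max
        with pytest.warns(UserWarning, match="boundary"):
            k, _ = estimate_k(O, T, k_max=2.0)
        assert k == pytest.approx(2.0, abs=0.01)


# ---------------------------------------------------------------- fragments

class TestFragmentRd:
    def test_whole_unit_fragment_equals_unit_rd(self, rng):
        n = 40
        T = random_distribution(rng, n)
        O = random_distribution(rng, n)
        R = uniform_profile(n)
        whole = FragmentSpec(0, n)
        assert fragment_rd(T, O, R, whole).rd == pytest.approx(rd(O, T, R).rd, abs=1e-12)

    def test_proportional_slice_gives_zero(self, rng):
        n = 30
        T = random_distribution(rng, n)
        O = T.copy()
        O[10:20] = 2.0 * T[10:20]  # proportional on the fragment after renorm
        O = O / O.sum()
        status = fragment_rd(T, O, uniform_profile(n), FragmentSpec(10, 20))
        assert status.rd == pytest.approx(0.0, abs=1e-9)

    def test_single_residue_fragment_rejected(self, rng):
        T = random_distribution(rng, 10)
        with pytest.raises(ValueError, match="at least 2"):
            fragment_rd(T, T, uniform_profile(10), FragmentSpec(3, 4))

    def test_out_of_range_fragment_rejected(self, rng):
        T = random_distribution(rng, 10)
        with pytest.raises(ValueError, match="outside"):
            fragment_rd(T, T, uniform_profile(10), FragmentSpec(5, 15))


# ---------------------------------------------------------------- pipeline invariance

class TestRigidMotionInvariance:
    def test_rd_and_k_invariant(self, micelle_model):
        base = unit_profiles(micelle_model)
        base_rd = rd(base.O, base.T, base.R).rd
        rng = np.random.default_rng(11)
        for i in range(3):
            R = Rotation.random(random_state=100 + i).as_matrix()
            shift = rng.uniform(-50, 50, size=3)
            moved = EffectiveAtomModel(
                micelle_model.residues,
                micelle_model.coords @ R.T + shift,
                micelle_model.hydrophobicity,
            )
            prof = unit_profiles(moved)
            assert rd(prof.O, prof.T, prof.R).rd == pytest.approx(base_rd, abs=1e-6)
            assert prof.K_of_M == pytest.approx(base.K_of_M, abs=1e-6)
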