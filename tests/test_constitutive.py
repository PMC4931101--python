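"""Constitutive-law tests: invariants, closed-form oracles, stress consistency."""

import numpy as np
import pytest

from sbsim.constitutive import (
    FiberDirections,
    InvalidDeformationError,
    MaterialParams,
    TISSUE_REGISTRY,
    cauchy_stress,
    compute_kinematics,
    registry_from_config,
    registry_to_config,
    strain_energy,
    tissue,
)

E1 = np.array([1.0, 0.0, 0.0])
E2 = np.array([0.0, 1.0, 0.0])
FIBERS = FiberDirections(E1, E2)


def random_admissible_F(rng, scale=0.08):
    """Random deformation gradient with moderate strain and det > 0."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3)
    return F


class TestKinematics:
    def test_identity_state(self):
        kin = compute_kinematics(np.eye(3), FIBERS)
        assert kin.J == pytest.approx(1.0)
        assert kin.I1bar == pytest.approx(3.0)
        assert kin.I2bar == pytest.approx(3.0)
        assert kin.I4bar == pytest.approx(1.0)
        assert kin.I6bar == pytest.approx(1.0)

    def test_fibre_invariant_is_squared_stretch(self):
        lam = 1.05
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        kin = compute_kinematics(F, FIBERS)
        assert kin.I4bar == pytest.approx(lam**2, abs=1e-10)

    def test_volumetric_scaling_of_first_invariant(self):
        rng = np.random.default_rng(0)
        A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        F = A * (2.0 / np.linalg.det(A)) ** (1.0 / 3.0)  # det = 2
        kin = compute_kinematics(F, FIBERS)
        assert np.linalg.det(F) == pytest.approx(2.0)
        assert kin.I1bar == pytest.approx(np.trace(F.T @ F) * 2.0 ** (-2.0 / 3.0), rel=1e-12)

    def test_modified_tensor_is_unimodular(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            kin = compute_kinematics(random_admissible_F(rng), FIBERS)
            assert np.linalg.det(kin.Cbar) == pytest.approx(1.0, abs=1e-10)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(InvalidDeformationError):
            compute_kinematics(np.diag([-1.0, 1.0, 1.0]), FIBERS)


class TestRegistry:
    def test_seven_tissues(self):
        assert set(TISSUE_REGISTRY) == {
            "cornea",
            "limbus",
            "sclera",
            "lens_cortex",
            "lens_nucleus",
            "lens_capsule",
            "nerve",
        }

    def test_parameter_values(self):
        scl = tissue("sclera")
        assert (scl.D_penalty, scl.C1, scl.C2) == (1e-5, 35.0, -32.0)
        assert scl.k1 == scl.k3 == 0.0
        cor = tissue("cornea")
        assert (cor.k1, cor.k2) == (0.234, 29.917)
        assert (cor.k3, cor.k4) == (0.234, 29.917)
        cap = tissue("lens_capsule")
        assert cap.k1 == pytest.approx(3.39e-2)
        assert tissue("nerve").C1 == pytest.approx(50.335e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams("sclera", -1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            MaterialParams("sclera", 1.0, 1.0, 0.0, k1=-0.1)
        with pytest.raises(ValueError):
            MaterialParams("retina", 1.0, 1.0, 0.0)

    def test_config_roundtrip(self):
        block = registry_to_config()
        back = registry_from_config(block)
        assert back == TISSUE_REGISTRY


class TestStrainEnergy:
    @pytest.mark.parametrize("label", sorted(TISSUE_REGISTRY))
    def test_reference_state_energy_free(self, label):
        kin = compute_kinematics(np.eye(3), FIBERS)
        assert strain_energy(kin, tissue(label)) == pytest.approx(0.0, abs=1e-14)

    def test_sclera_matches_mooney_rivlin_closed_form(self):
        """Uniaxial isochoric stretch: Mooney-Rivlin closed form plus the
        documented biaxial range guard (0.25% here)."""
        from sbsim.constitutive import matrix_range_guard_energy

        lam = 1.05
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        kin = compute_kinematics(F, None)
        p = tissue("sclera")
        I1 = lam**2 + 2.0 / lam
        I2 = 2.0 * lam + lam**-2
        expected = 0.5 * p.C1 * (I1 - 3.0) + 0.5 * p.C2 * (I2 - 3.0)
        guard = float(matrix_range_guard_energy(I1, p.C1, p.C2))
        assert guard < 0.005 * expected  # negligible inside the fitted range
        assert strain_energy(kin, p) == pytest.approx(expected + guard, rel=1e-12)

    def test_cornea_fibre_term_closed_form(self):
        lam = 1.02
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        fibers = FiberDirections(E1, E2)
        kin = compute_kinematics(F, fibers)
        p = tissue("cornea")
        fibre_1 = p.k1 / (2.0 * p.k2) * (np.exp(p.k2 * (lam**2 - 1.0) ** 2) - 1.0)
        # second family along e2 is in compression (I6 < 1): inactive
        matrix = 0.5 * p.C1 * (kin.I1bar - 3.0)
        assert strain_energy(kin, p) == pytest.approx(matrix + fibre_1, rel=1e-12)

    def test_fibres_inactive_in_compression(self):
        lam = 0.97  # fibre shortened
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        p_fib = tissue("limbus")
        p_matrix = MaterialParams("limbus", p_fib.D_penalty, p_fib.C1, p_fib.C2)
        kin = compute_kinematics(F, FIBERS)
        assert strain_energy(kin, p_fib) == pytest.approx(strain_energy(kin, p_matrix), rel=1e-14)

    def test_vanishing_exponent_quadratic_limit(self):
        lam = 1.03
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        kin = compute_kinematics(F, FIBERS)
        p = MaterialParams("cornea", 1e-5, 0.0, 0.0, k1=0.5, k2=0.0)
        assert strain_energy(kin, p) == pytest.approx(0.25 * (lam**2 - 1.0) ** 2, rel=1e-10)

    @pytest.mark.parametrize("label", sorted(set(TISSUE_REGISTRY) - {"sclera"}))
    def test_nonnegative_over_operating_range(self, label):
        """Psi >= 0 for |I1bar - 3| <= 0.3 for every C2 >= 0 tissue."""
        from sbsim.constitutive import energy_nonnegativity_report

        rep = energy_nonnegativity_report(tissue(label), n_samples=300, seed=7)
        assert rep["n_in_range"] > 100
        assert rep["n_violations"] == 0

    def test_sclera_guard_restores_nonnegativity(self):
        """The bare C2 = -32 MPa Mooney-Rivlin fit goes negative under
        biaxial stretch inside |I1bar - 3| <= 0.3; with the range guard the
        implemented energy stays non-negative there."""
        from sbsim.constitutive import energy_nonnegativity_report

        p = tissue("sclera")
        # bare-fit witness at equibiaxial 10% stretch (scalar arithmetic)
        lam = 1.1
        I1 = 2 * lam**2 + lam**-4
        I2 = lam**4 + 2 * lam**-2
        bare = 0.5 * p.C1 * (I1 - 3.0) + 0.5 * p.C2 * (I2 - 3.0)
        assert bare < 0.0
        kin = compute_kinematics(np.diag([lam, lam, lam**-2]))
        assert strain_energy(kin, p) > 0.0
        rep = energy_nonnegativity_report(p, n_samples=500, seed=7)
        assert rep["n_in_range"] > 100
        assert rep["n_violations"] == 0

    def test_objectivity_under_rotations(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        F = random_admissible_F(rng)
        kin = compute_kinematics(F, FIBERS)
        p = tissue("cornea")
        base = strain_energy(kin, p)
        for Q in Rotation.random(100, rng=rng).as_matrix():
            kin_q = compute_kinematics(Q @ F, FIBERS)
            assert strain_energy(kin_q, p) == pytest.approx(base, abs=1e-10)

    def test_material_symmetry_family_swap(self):
        rng = np.random.default_rng(4)
        p = tissue("cornea")
        p_swapped = MaterialParams("cornea", p.D_penalty, p.C1, p.C2, p.k3, p.k4, p.k1, p.k2)
        for _ in range(10):
            F = random_admissible_F(rng)
            kin = compute_kinematics(F, FiberDirections(E1, E2))
            kin_swap = compute_kinematics(F, FiberDirections(E2, E1))
            assert strain_energy(kin_swap, p_swapped) == pytest.approx(strain_energy(kin, p), rel=1e-12)


class TestCauchyStress:
    @pytest.mark.parametrize("label", sorted(TISSUE_REGISTRY))
    def test_reference_state_stress_free(self, label):
        kin = compute_kinematics(np.eye(3), FIBERS)
        assert np.allclose(cauchy_stress(kin, tissue(label)), 0.0, atol=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        kin = compute_kinematics(random_admissible_F(rng), FIBERS)
        sig = cauchy_stress(kin, tissue("cornea"))
        assert np.allclose(sig, sig.T, atol=1e-10)

    @pytest.mark.parametrize("label", sorted(TISSUE_REGISTRY))
    def test_matches_finite_difference_of_energy(self, label):
        """Analytic stress equals the FD gradient of Psi (20 states/tissue)."""
        rng = np.random.default_rng(11)
        p = tissue(label)
        for _ in range(20):
            F = random_admissible_F(rng)
            sig = cauchy_stress(compute_kinematics(F, FIBERS), p)
            sig_fd = finite_difference_cauchy(F, p)
            scale = max(np.abs(sig_fd).max(), 1e-6)
            assert np.abs(sig - sig_fd).max() <= 1e-4 * scale

    def test_sclera_equibiaxial_closed_form(self):
        """Deviatoric biaxial response matches the incompressible
        Mooney-Rivlin + range-guard closed form (the penalty pressure
        cancels in sigma_11 - sigma_33)."""
        from sbsim.constitutive import _matrix_range_guard_dpsi

        lam = 1.03
        F = np.diag([lam, lam, lam**-2])
        p = tissue("sclera")
        sig = cauchy_stress(compute_kinematics(F, None), p)
        s11 = p.C1 * (lam**2 - lam**-4) - p.C2 * (lam**-2 - lam**4)
        I1b = 2.0 * lam**2 + lam**-4
        s11 += 2.0 * float(_matrix_range_guard_dpsi(I1b, p.C1, p.C2)) * (lam**2 - lam**-4)
        assert sig[0, 0] - sig[2, 2] == pytest.approx(s11, rel=1e-9)
        assert sig[1, 1] - sig[2, 2] == pytest.approx(s11, rel=1e-9)
        assert sig[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_sclera_biaxial_response_is_monotone(self):
        """The guard removes the bare fit's biaxial softening: stress rises
        monotonically with equibiaxial stretch."""
        p = tissue("sclera")
        prev = -np.inf
        for lam in np.linspace(1.0, 1.15, 60):
            F = np.diag([lam, lam, lam**-2])
            sig = cauchy_stress(compute_kinematics(F, None), p)
            s = sig[0, 0] - sig[2, 2]
            assert s > prev
            prev = s


def finite_difference_cauchy(F, params, h=1e-6):
    """Independent stress oracle: central FD of Psi w.r.t. F, pushed to Cauchy.

    P_iJ = dPsi/dF_iJ, sigma = P F^T / J.
    """
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            ep = strain_energy(compute_kinematics(Fp, FIBERS), params)
            em = strain_energy(compute_kinematics(Fm, FIBERS), params)
            P[i, j] = (ep - em) / (2.0 * h)
    sig = P @ F.T / np.linalg.det(F)
    return 0.5 * (sig + sig.T)
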