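import numpy as np
import pytest

from tmjsim.fem import (
    ElementInversionError,
    FemBody,
    MooneyRivlinMaterial,
    cauchy_stress,
    deformation_gradient,
    lumped_mass,
    regularize_deformation,
    strain_energy_density,
    von_mises,
)
from tmjsim.mesh_io import TetMesh
from tmjsim.synthetic import generate_disk_mesh

MAT = MooneyRivlinMaterial(C1=9e5, C2=9e2)


def _rand_rotation(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q * np.sign(np.linalg.det(Q))


class TestMaterial:
    def test_defaults_and_kappa(self):
        assert MAT.kappa == pytest.approx(1000 * 9e5)
        with pytest.raises(ValueError):
            MooneyRivlinMaterial(C1=-1.0)
        with pytest.raises(ValueError):
            MooneyRivlinMaterial(C1=1e6, kappa=1e6)

    def test_energy_zero_at_identity_and_rotation(self):
        assert strain_energy_density(np.eye(3), MAT) == pytest.approx(0.0, abs=1e-9)
        R = _rand_rotation(3)
        assert strain_energy_density(R, MAT) == pytest.approx(0.0, abs=1e-6)

    def test_isochoric_uniaxial_energy(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        I1 = lam**2 + 2 / lam
        I2 = lam**-2 + 2 * lam
        expected = 9e5 * (I1 - 3) + 9e2 * (I2 - 3)  # J=1: no volumetric term
        assert strain_energy_density(F, MAT) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(96085.0, abs=1.0)

    def test_incompressible_uniaxial_stress(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        sig = cauchy_stress(F, MAT)
        analytic = 2 * (lam**2 - 1 / lam) * (9e5 + 9e2 / lam)
        assert sig[0, 0] - sig[1, 1] == pytest.approx(analytic, rel=1e-9)
        assert analytic == pytest.approx(1.0929e6, rel=1e-3)

    def test_deformation_gradient_cases(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert np.allclose(deformation_gradient(ref, ref), np.eye(3))
        s = 1.7
        F = deformation_gradient(ref, s * ref)
        assert np.allclose(F, s * np.eye(3))
        assert np.linalg.det(F) == pytest.approx(s**3)
        lam = 1.2
        stretch = ref * np.array([lam, lam**-0.5, lam**-0.5])
        assert np.linalg.det(deformation_gradient(ref, stretch)) == pytest.approx(1.0)

    def test_von_mises_closed_forms(self):
        s = 3.7e5
        assert von_mises(np.diag([s, 0, 0])) == pytest.approx(s, rel=1e-12)
        tau = np.zeros((3, 3)); tau[0, 1] = tau[1, 0] = s
        assert von_mises(tau) == pytest.approx(np.sqrt(3) * s, rel=1e-12)
        assert von_mises(np.diag([s, s, s])) == pytest.approx(0.0, abs=1e-6)


class TestForcesAndTangent:
    def test_undeformed_forces_zero(self, mm_tet_body):
        f = mm_tet_body.internal_forces()
        assert np.allclose(f, 0, atol=1e-12)

    def test_force_sum_zero_any_deformation(self, mm_tet_body):
        rng = np.random.default_rng(2)
        x = mm_tet_body.mesh.nodes + rng.normal(scale=5e-5, size=(4, 3))
        f = mm_tet_body.internal_forces(x)
        assert np.abs(f.sum(axis=0)).max() <= 1e-9 * np.abs(f).max()

    def test_forces_are_energy_gradient(self, mm_tet_body):
        rng = np.random.default_rng(4)
        x = mm_tet_body.mesh.nodes + rng.normal(scale=5e-5, size=(4, 3))
        f = mm_tet_body.internal_forces(x)
        h = 1e-9
        for idx in [(0, 0), (1, 2), (3, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h; xm[idx] -= h
            fd = -(mm_tet_body.strain_energy(xp) - mm_tet_body.strain_energy(xm)) / (2 * h)
            assert fd == pytest.approx(f[idx], rel=1e-4)

    def test_uniaxial_stress_recovery_single_tet(self):
        """Stretched tet recovers the incompressible analytic Cauchy stress."""
        lam = 1.2
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float) * 1e-3
        body = FemBody("t", TetMesh(ref, [[0, 1, 2, 3]]), MAT, total_mass=1e-6)
        from scipy.optimize import brentq

        def lateral(mu):
            F = np.diag([lam, mu, mu])
            return cauchy_stress(F, MAT)[1, 1]

        mu = brentq(lateral, 0.8, 1.0)
        x = ref * np.array([lam, mu, mu])
        sf = body.stress_recovery(x)
        assert sf.element_stress[0, 0, 0] == pytest.approx(1.0929e6, rel=0.02)

    def test_tangent_matches_fd_forces(self, mm_tet_body):
        rng = np.random.default_rng(6)
        x = mm_tet_body.mesh.nodes + rng.normal(scale=3e-5, size=(4, 3))
        K = mm_tet_body.tangent_stiffness(x).toarray()
        h = 1e-10
        Kfd = np.zeros((12, 12))
        for j in range(12):
            xp = x.ravel().copy(); xp[j] += h
            xm = x.ravel().copy(); xm[j] -= h
            Kfd[:, j] = -(mm_tet_body.internal_forces(xp.reshape(-1, 3))
                          - mm_tet_body.internal_forces(xm.reshape(-1, 3))).ravel() / (2 * h)
        assert np.abs(K - Kfd).max() <= 1e-4 * np.abs(Kfd).max()

    def test_tangent_symmetric_and_translation_nullspace(self, mm_tet_body):
        K = mm_tet_body.tangent_stiffness().toarray()
        assert np.abs(K - K.T).max() <= 1e-6 * max(np.abs(K).max(), 1e-30)
        t = np.tile([1.0, 0.0, 0.0], 4)
        assert np.abs(K @ t).max() <= 1e-6 * np.abs(K).max()

    def test_tangent_linear_in_material_constants(self, mm_tet_body):
        s = 3.0
        mat2 = MooneyRivlinMaterial(C1=s * MAT.C1, C2=s * MAT.C2, kappa=s * MAT.kappa)
        body2 = FemBody("t2", mm_tet_body.mesh, mat2, total_mass=1e-6)
        K1 = mm_tet_body.tangent_stiffness().toarray()
        K2 = body2.tangent_stiffness().toarray()
        assert np.allclose(K2, s * K1, rtol=1e-6, atol=1e-9 * np.abs(K1).max())

    def test_objectivity(self, mm_tet_body):
        rng = np.random.default_rng(8)
        x = mm_tet_body.mesh.nodes + rng.normal(scale=5e-5, size=(4, 3))
        R = _rand_rotation(9)
        W1 = mm_tet_body.strain_energy(x)
        W2 = mm_tet_body.strain_energy(x @ R.T)
        assert W2 == pytest.approx(W1, rel=1e-9)
        s1 = mm_tet_body.stress_recovery(x)
        s2 = mm_tet_body.stress_recovery(x @ R.T)
        assert s2.nodal_von_mises == pytest.approx(s1.nodal_von_mises, rel=1e-9)

    def test_patch_test_uniform_stretch(self):
        """A multi-element block under uniform stretch reproduces the
        single-element stress field."""
        mesh = generate_disk_mesh((3.0, 3.0), 2.0, 2.0, 1.0)
        mesh = TetMesh(mesh.nodes * 1e-3, mesh.tets)
        body = FemBody("blk", mesh, MAT, total_mass=1e-6)
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        x = mesh.nodes @ F.T
        sf = body.stress_recovery(x)
        single = cauchy_stress(F, MAT)
        assert np.allclose(sf.element_stress, single[None], rtol=1e-6)

    def test_inversion_raises_by_default(self, mm_tet_body):
        x = mm_tet_body.mesh.nodes.copy()
        x[3, 2] = -1e-3  # flip node through the base plane
        with pytest.raises(ElementInversionError):
            mm_tet_body.internal_forces(x)

    def test_inversion_regularized_when_allowed(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float) * 1e-3
        body = FemBody("t", TetMesh(ref, [[0, 1, 2, 3]]), MAT, total_mass=1e-6,
                       allow_inversion=True)
        x = ref.copy(); x[3, 2] = -1e-3
        f = body.internal_forces(x)
        assert np.all(np.isfinite(f))
        assert f[3, 2] > 0  # pushes the flipped node back up

    def test_regularize_deformation_projects_to_floor(self):
        F = np.diag([1.0, 1.0, -0.5])[None]
        Fr = regularize_deformation(F, floor=0.4)
        s = np.linalg.svd(Fr[0], compute_uv=False)
        assert np.linalg.det(Fr[0]) > 0
        assert s.min() >= 0.4 - 1e-12


class TestMass:
    def test_single_tet_equal_split(self, regular_tet):
        m = lumped_mass(regular_tet, density=1000.0)
        V = regular_tet.volume
        assert np.allclose(m, 1000.0 * V / 4)

    def test_disk_mass_target(self, anatomy):
        for fb in anatomy.system.fem_bodies.values():
            assert fb.node_mass.sum() == pytest.approx(0.006, rel=1e-9)

    def test_refinement_conserves_mass(self):
        coarse = generate_disk_mesh((4.0, 5.0), 2.0, 2.0, 1.0)
        fine = generate_disk_mesh((4.0, 5.0), 2.0, 2.0, 0.5)
        rho = 1234.0
        m_c = lumped_mass(coarse, rho).sum()
        m_f = lumped_mass(fine, rho).sum()
        # same analytic solid meshed at two resolutions: mass tracks volume
        assert m_c == pytest.approx(rho * coarse.volume, rel=1e-9)
        assert m_f == pytest.approx(rho * fine.volume, rel=1e-9)

    def test_energy_consistency_along_perturbation(self, mm_tet_body):
        rng = np.random.default_rng(11)
        x = mm_tet_body.mesh.nodes + rng.normal(scale=3e-5, size=(4, 3))
        direction = rng.normal(size=(4, 3))
        direction /= np.linalg.norm(direction)
        h = 1e-10
        dW = (mm_tet_body.strain_energy(x + h * direction)
              - mm_tet_body.strain_energy(x - h * direction)) / (2 * h)
        f = mm_tet_body.internal_forces(x)
        assert np.vdot(f, direction) == pytest.approx(-dW, rel=1e-3)
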