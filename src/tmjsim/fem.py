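"""First-order tetrahedral FEM for the TMJ disks.

The disk is a nearly incompressible hyperelastic solid.  The two-term
Mooney-Rivlin energy W = C1 (I1 - 3) + C2 (I2 - 3) is evaluated on the
*isochoric* invariants and extended with a volumetric penalty:

    W = C1 (Ib1 - 3) + C2 (Ib2 - 3) + kappa/2 (J - 1)^2,

where Ib1, Ib2 are the invariants of Bbar = J^(-2/3) B, B = F F^T the
left Cauchy-Green tensor, and J = det F.  The plain two-term law has no
volumetric response and is ill-posed for a solid; the penalty with
kappa = 1000 C1 enforces near-incompressibility (nu_eff ~ 0.4995).

Elements are constant-strain linear tets.  Nodal forces come from the
analytic Cauchy/Kirchhoff stress; the tangent stiffness is a central
finite-difference linearization of those analytic forces, vectorized
across elements and symmetrized after assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_io import TetMesh, TriMesh

__all__ = [
    "MooneyRivlinMaterial",
    "FemBody",
    "StressField",
    "deformation_gradient",
    "strain_energy_density",
    "cauchy_stress",
    "lumped_mass",
    "von_mises",
    "ElementInversionError",
]

_EYE = np.eye(3)


def _inv33(A):
    """Batched explicit 3x3 inverse (much faster than LAPACK for stacks)."""
    a = A[..., 0, 0]; b = A[..., 0, 1]; c = A[..., 0, 2]
    d = A[..., 1, 0]; e = A[..., 1, 1]; f = A[..., 1, 2]
    g = A[..., 2, 0]; h = A[..., 2, 1]; i = A[..., 2, 2]
    co = np.empty_like(A)
    co[..., 0, 0] = e * i - f * h
    co[..., 0, 1] = c * h - b * i
    co[..., 0, 2] = b * f - c * e
    co[..., 1, 0] = f * g - d * i
    co[..., 1, 1] = a * i - c * g
    co[..., 1, 2] = c * d - a * f
    co[..., 2, 0] = d * h - e * g
    co[..., 2, 1] = b * g - a * h
    co[..., 2, 2] = a * e - b * d
    det = a * co[..., 0, 0] + b * co[..., 1, 0] + c * co[..., 2, 0]
    return co / det[..., None, None]


def _det33(A):
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


class ElementInversionError(RuntimeError):
    """det F <= 0 in one or more elements."""

    def __init__(self, element_ids):
        self.element_ids = np.atleast_1d(element_ids)
        super().__init__(f"inverted elements: {self.element_ids.tolist()[:20]}")


@dataclass(frozen=True)
class MooneyRivlinMaterial:
    """Nearly incompressible Mooney-Rivlin material.

    C1, C2 in Pa; ``kappa`` is the volumetric penalty bulk modulus
    (defaults to 1000 C1); density in kg/m^3.
    """

    C1: float = 9.0e5
    C2: float = 9.0e2
    kappa: float | None = None
    density: float = 1000.0

    def __post_init__(self):
        if self.C1 <= 0:
            raise ValueError("C1 must be positive")
        if self.C2 < 0:
            raise ValueError("C2 must be non-negative")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 1000.0 * self.C1)
        if self.kappa < 100.0 * self.C1:
            raise ValueError("kappa must be >= 100 C1 for near-incompressibility")


def deformation_gradient(ref_nodes, cur_nodes):
    """F = Ds Dm^-1 for one or many constant-strain tets.

    ``ref_nodes``/``cur_nodes`` have shape (..., 4, 3).
    """
    ref = np.asarray(ref_nodes, float)
    cur = np.asarray(cur_nodes, float)
    Dm = np.swapaxes(ref[..., 1:, :] - ref[..., :1, :], -1, -2)
    Ds = np.swapaxes(cur[..., 1:, :] - cur[..., :1, :], -1, -2)
    return Ds @ np.linalg.inv(Dm)


def _invariants(F):
    J = _det33(F)
    B = F @ np.swapaxes(F, -1, -2)
    Jm23 = J ** (-2.0 / 3.0)
    Bbar = Jm23[..., None, None] * B
    I1b = np.trace(Bbar, axis1=-2, axis2=-1)
    BB = Bbar @ Bbar
    I2b = 0.5 * (I1b**2 - np.trace(BB, axis1=-2, axis2=-1))
    return J, Bbar, BB, I1b, I2b


def strain_energy_density(F, material: MooneyRivlinMaterial):
    """W(F) in J/m^3; zero at F = I and under pure rotations."""
    J, _, _, I1b, I2b = _invariants(np.asarray(F, float))
    if np.any(J <= 0):
        raise ElementInversionError(np.nonzero(np.atleast_1d(J) <= 0)[0])
    return (
        material.C1 * (I1b - 3.0)
        + material.C2 * (I2b - 3.0)
        + 0.5 * material.kappa * (J - 1.0) ** 2
    )


def kirchhoff_stress(F, material: MooneyRivlinMaterial):
    """Kirchhoff stress tau = J sigma for the penalty-split Mooney-Rivlin law."""
    J, Bbar, BB, I1b, _ = _invariants(F)
    M = (material.C1 + material.C2 * I1b[..., None, None]) * Bbar - material.C2 * BB
    trM = np.trace(M, axis1=-2, axis2=-1)
    tau = 2.0 * (M - (trM / 3.0)[..., None, None] * _EYE)
    tau = tau + (material.kappa * J * (J - 1.0))[..., None, None] * _EYE
    return tau


def cauchy_stress(F, material: MooneyRivlinMaterial):
    F = np.asarray(F, float)
    J = _det33(F)
    return kirchhoff_stress(F, material) / J[..., None, None]


def von_mises(sigma):
    """sqrt(3/2 dev(s):dev(s)) for (...,3,3) stress tensors."""
    sigma = np.asarray(sigma, float)
    dev = sigma - (np.trace(sigma, axis1=-2, axis2=-1) / 3.0)[..., None, None] * _EYE
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def lumped_mass(mesh: TetMesh, density: float) -> np.ndarray:
    """Per-node mass: each tet's mass split equally onto its 4 nodes."""
    m = np.zeros(len(mesh.nodes))
    contrib = density * mesh.signed_volumes() / 4.0
    for k in range(4):
        np.add.at(m, mesh.tets[:, k], contrib)
    return m


@dataclass
class StressField:
    """Recovered Cauchy stresses: per-element tensors and nodal averages."""

    element_stress: np.ndarray  # (E,3,3)
    nodal_stress: np.ndarray  # (N,3,3) volume-weighted averages
    nodal_von_mises: np.ndarray  # (N,)
    nodal_max_principal: np.ndarray  # (N,)


def regularize_deformation(F, floor: float = 0.45):
    """Project degenerate/inverted deformation gradients to a safe cone.

    Signed SVD (Irving-style invertible FEM): the rotation factors are
    kept, singular values are clamped to ``floor`` (inversion shows up
    as a negative smallest singular value and is clamped away).  The
    stress computed from the projected F is finite and strongly
    repulsive through the volumetric penalty, driving the element back
    toward an uninverted state.
    """
    F = np.asarray(F, float)
    U, S, Vt = np.linalg.svd(F)
    # make U, V proper rotations; push any reflection into the last
    # singular value so inversion appears as S[..., 2] < 0
    du = np.linalg.det(U)
    dv = np.linalg.det(Vt)
    U = U.copy(); Vt = Vt.copy(); S = S.copy()
    U[du < 0, :, 2] *= -1.0
    S[du < 0, 2] *= -1.0
    Vt[dv < 0, 2, :] *= -1.0
    S[dv < 0, 2] *= -1.0
    S = np.clip(S, floor, None)
    return np.einsum("...ij,...j,...jk->...ik", U, S, Vt)


class FemBody:
    """A deformable disk: tet mesh + material + nodal kinematic state.

    ``allow_inversion=False`` (default) aborts on element inversion with
    a diagnostic listing the element ids; with ``allow_inversion=True``
    degenerate elements are evaluated on an SVD-projected deformation
    gradient instead (see :func:`regularize_deformation`) and the
    simulation continues.
    """

    def __init__(self, name: str, mesh: TetMesh, material: MooneyRivlinMaterial,
                 total_mass: float | None = None, allow_inversion: bool = False):
        self.allow_inversion = allow_inversion
        self.inversion_events = 0
        self.name = name
        self.mesh = mesh
        ref_volume = mesh.volume
        if total_mass is not None:
            material = MooneyRivlinMaterial(
                C1=material.C1, C2=material.C2, kappa=material.kappa,
                density=total_mass / ref_volume,
            )
        self.material = material
        self.ref_volume = ref_volume
        self.positions = mesh.nodes.copy()
        self.velocities = np.zeros_like(self.positions)
        self.node_mass = lumped_mass(mesh, self.material.density)

        self.surface, self.surface_nodes = mesh.surface()
        edges = mesh.nodes[mesh.tets[:, 1:]] - mesh.nodes[mesh.tets[:, :1]]
        self.min_edge = float(np.linalg.norm(edges, axis=2).min())
        p = mesh.nodes[mesh.tets]
        Dm = np.swapaxes(p[:, 1:] - p[:, :1], -1, -2)
        self._Dm_inv = np.linalg.inv(Dm)
        self._V0 = mesh.signed_volumes()
        self._n_dof = 3 * len(mesh.nodes)
        # cached sparse assembly pattern for the tangent
        e = mesh.tets
        cols = (3 * e[:, :, None] + np.arange(3)[None, None, :]).reshape(len(e), 12)
        self._rows = np.repeat(cols, 12, axis=1).ravel()
        self._cols = np.tile(cols, (1, 12)).ravel()

    # --- kinematics / forces -------------------------------------------
    def deformation_gradients(self, positions=None):
        x = self.positions if positions is None else positions
        cur = x[self.mesh.tets]
        Ds = np.swapaxes(cur[:, 1:] - cur[:, :1], -1, -2)
        return Ds @ self._Dm_inv

    def _guard_F(self, F, j_floor: float = 0.3):
        """Abort on inversion, or project degenerate elements if allowed."""
        J = _det33(F)
        if not self.allow_inversion:
            inverted = J <= 0
            if np.any(inverted):
                raise ElementInversionError(np.nonzero(inverted)[0])
            return F
        bad = J <= j_floor
        if np.any(bad):
            F = F.copy()
            F[bad] = regularize_deformation(F[bad])
            self.inversion_events += int(np.count_nonzero(bad))
        return F

    def _element_forces(self, positions, check_inversion=True):
        """(E,4,3) nodal forces from the analytic Kirchhoff stress."""
        F = self._guard_F(self.deformation_gradients(positions))
        tau = kirchhoff_stress(F, self.material)
        # P = tau F^-T ; dW/dDs = V0 P Dm^-T (gradient wrt nodes 1..3)
        P = tau @ _inv33(np.swapaxes(F, -1, -2))
        G = self._V0[:, None, None] * (P @ np.swapaxes(self._Dm_inv, -1, -2))
        f = np.empty((len(F), 4, 3))
        f[:, 1:, :] = -np.swapaxes(G, -1, -2)
        f[:, 0, :] = G.sum(axis=-1)
        return f

    def internal_forces(self, positions=None) -> np.ndarray:
        """Global (N,3) nodal internal forces (negative energy gradient)."""
        x = self.positions if positions is None else positions
        fe = self._element_forces(x)
        f = np.zeros_like(x)
        for k in range(4):
            np.add.at(f, self.mesh.tets[:, k], fe[:, k])
        return f

    def strain_energy(self, positions=None) -> float:
        F = self._guard_F(self.deformation_gradients(positions))
        return float(np.sum(self._V0 * strain_energy_density(F, self.material)))

    def tangent_stiffness(self, positions=None, fd_step: float | None = None) -> sp.csr_matrix:
        """Sparse symmetric stiffness K = -d f / d x at the given state.

        Central finite differences of the analytic element forces,
        vectorized across elements, assembled and symmetrized.
        """
        x = self.positions if positions is None else positions
        if fd_step is None:
            edge = np.linalg.norm(
                self.mesh.nodes[self.mesh.tets[:, 1]] - self.mesh.nodes[self.mesh.tets[:, 0]],
                axis=1,
            ).mean()
            fd_step = 1e-6 * edge
        cur = x[self.mesh.tets].copy()  # (E,4,3)
        blocks = np.empty((len(cur), 12, 12))
        for a in range(4):
            for k in range(3):
                cur[:, a, k] += fd_step
                fp = self._element_forces_local(cur)
                cur[:, a, k] -= 2 * fd_step
                fm = self._element_forces_local(cur)
                cur[:, a, k] += fd_step
                blocks[:, :, 3 * a + k] = -((fp - fm) / (2 * fd_step)).reshape(len(cur), 12)
        K = sp.coo_matrix(
            (blocks.ravel(), (self._rows, self._cols)), shape=(self._n_dof, self._n_dof)
        ).tocsr()
        return (K + K.T) * 0.5

    def _element_forces_local(self, cur):
        """Forces from explicit per-element node positions (E,4,3)."""
        Ds = np.swapaxes(cur[:, 1:] - cur[:, :1], -1, -2)
        F = self._guard_F(Ds @ self._Dm_inv)
        tau = kirchhoff_stress(F, self.material)
        P = tau @ _inv33(np.swapaxes(F, -1, -2))
        G = self._V0[:, None, None] * (P @ np.swapaxes(self._Dm_inv, -1, -2))
        f = np.empty((len(F), 4, 3))
        f[:, 1:, :] = -np.swapaxes(G, -1, -2)
        f[:, 0, :] = G.sum(axis=-1)
        return f

    # --- stress recovery ------------------------------------------------
    def stress_recovery(self, positions=None) -> StressField:
        """Element Cauchy stresses and volume-averaged nodal tensors."""
        x = self.positions if positions is None else positions
        F = self._guard_F(self.deformation_gradients(x))
        sigma = cauchy_stress(F, self.material)
        w = np.abs(self._V0)
        nodal = np.zeros((len(self.mesh.nodes), 3, 3))
        wsum = np.zeros(len(self.mesh.nodes))
        for k in range(4):
            np.add.at(nodal, self.mesh.tets[:, k], w[:, None, None] * sigma)
            np.add.at(wsum, self.mesh.tets[:, k], w)
        nodal /= np.where(wsum > 0, wsum, 1.0)[:, None, None]
        vm = von_mises(nodal)
        eig = np.linalg.eigvalsh(nodal)
        return StressField(
            element_stress=sigma,
            nodal_stress=nodal,
            nodal_von_mises=vm,
            nodal_max_principal=eig[:, -1],
        )

    # --- surface access -------------------------------------------------
    def world_surface(self, positions=None) -> TriMesh:
        x = self.positions if positions is None else positions
        return TriMesh(x, self.surface.faces)
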