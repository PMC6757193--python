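"""Rigid bodies: the dynamic mandible and the static skull/hyoid.

Pose is position of the centre of mass plus a unit quaternion (scalar
first); twist is linear velocity of the COM plus world-frame angular
velocity.  Inertia comes from the exact divergence-theorem integrals
over the (watertight) surface mesh under a uniform-density assumption,
scaled to an assumed total mass (the mandible uses 200 g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_io import TriMesh

__all__ = ["RigidBody", "inertia_from_mesh", "quat_rotate", "quat_multiply", "quat_from_rotvec"]


def quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_from_rotvec(phi):
    """Exponential map: rotation vector -> unit quaternion."""
    phi = np.asarray(phi, float)
    angle = np.linalg.norm(phi)
    if angle < 1e-12:
        return np.array([1.0, *(0.5 * phi)]) / np.sqrt(1 + 0.25 * angle**2)
    axis = phi / angle
    return np.array([np.cos(angle / 2), *(np.sin(angle / 2) * axis)])


def quat_to_matrix(q):
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_rotate(q, v):
    return quat_to_matrix(q) @ np.asarray(v, float)


def skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def cross3(a, b):
    """Cross product of two 3-vectors (avoids np.cross call overhead)."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def inertia_from_mesh(mesh: TriMesh, mass: float):
    """COM and inertia tensor (about COM) of a uniform solid bounded by ``mesh``.

    Exact polyhedral mass-property integrals (divergence theorem), via
    trimesh.  The mesh must be watertight; a negative enclosed volume
    (inward orientation) is fixed automatically.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise ValueError(
            "inertia_from_mesh needs a watertight mesh; repair the surface "
            "(fill holes / remove duplicate faces) before use"
        )
    if tm.volume < 0:
        tm.invert()
    props = tm.mass_properties
    volume = float(props["volume"])
    if volume <= 0:
        raise ValueError("mesh encloses non-positive volume")
    density = mass / volume
    com = np.asarray(props["center_mass"], float)
    inertia = np.asarray(props["inertia"], float) * density  # trimesh uses density 1
    inertia = 0.5 * (inertia + inertia.T)
    eig = np.linalg.eigvalsh(inertia)
    if eig.min() <= 0:
        raise ValueError("computed inertia is not positive definite")
    return com, inertia


@dataclass
class RigidBody:
    """A rigid body with pose/twist state.

    ``position`` locates the COM in world; local points are expressed
    relative to the COM in the body frame.
    """

    name: str
    mesh: TriMesh | None = None
    mass: float = 0.0
    inertia: np.ndarray = field(default_factory=lambda: np.eye(3))
    dynamic: bool = False
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def from_mesh(cls, name, mesh: TriMesh, mass: float, dynamic: bool = True):
        """Build a dynamic body with mesh-derived inertia, COM at the origin.

        The mesh is re-expressed relative to its COM so that local points
        are COM-relative; ``position`` is initialized to the world COM.
        """
        com, inertia = inertia_from_mesh(mesh, mass)
        local = TriMesh(mesh.vertices - com, mesh.faces)
        body = cls(name=name, mesh=local, mass=mass, inertia=inertia, dynamic=dynamic)
        body.position = com.copy()
        return body

    # --- kinematics -----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion)

    def world_point(self, local_point) -> np.ndarray:
        return self.position + self.rotation @ np.asarray(local_point, float)

    def local_point(self, world_point) -> np.ndarray:
        return self.rotation.T @ (np.asarray(world_point, float) - self.position)

    def point_velocity(self, local_point) -> np.ndarray:
        r = self.rotation @ np.asarray(local_point, float)
        return self.velocity + cross3(self.omega, r)

    def world_mesh(self, mesh: TriMesh | None = None) -> TriMesh:
        m = mesh if mesh is not None else self.mesh
        return m.transformed(self.rotation, self.position)

    def point_jacobian(self, world_point) -> np.ndarray:
        """3x6 map from twist [v; omega] to the velocity of a world point."""
        r = np.asarray(world_point, float) - self.position
        J = np.zeros((3, 6))
        J[:, :3] = np.eye(3)
        J[:, 3:] = -skew(r)
        return J

    def advance(self, dt: float):
        """Integrate pose with the current twist (exponential-map increment)."""
        self.position = self.position + dt * self.velocity
        dq = quat_from_rotvec(dt * self.omega)
        q = quat_multiply(dq, self.quaternion)
        self.quaternion = q / np.linalg.norm(q)

    def world_inertia(self) -> np.ndarray:
        R = self.rotation
        return R @ self.inertia @ R.T

    def kinetic_energy(self) -> float:
        if not self.dynamic:
            return 0.0
        return 0.5 * self.mass * self.velocity @ self.velocity + 0.5 * self.omega @ (
            self.world_inertia() @ self.omega
        )
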