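"""Elastic-foundation (EF) cartilage contact.

Articular cartilage is modelled as a thin elastic layer bonded to a
rigid substrate (condyle or fossa).  Contact pressure depends only on
the local penetration d of the opposing surface into the layer:

    p(d) = K ln(1 - d/h),    K = -(1 - nu) E / ((1 + nu)(1 - 2 nu)),

with layer thickness h, elastic modulus E and Poisson ratio nu
(defaults h = 0.4 mm, E = 2.7 MPa, nu = 0.49).  K is negative for
nu < 1/2, so p > 0 for 0 < d < h and diverges at full-layer
compression; the implementation caps d at 0.99 h.

Each penetrating vertex of the opposing body becomes one contact with
nodal force f = p(d) A n, where n is the outward substrate normal at
the nearest point and A splits the total penetrating patch area of the
opposing surface equally over its penetrating vertices.  In the
implicit solve each contact acts as a regularized unilateral point
constraint: force p(d) A along n with compliance 1/(A dp/dd),
equivalently an implicit spring of stiffness A dp/dd = -A K/(h-d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .mesh_io import TriMesh
from .surface import signed_distances

__all__ = [
    "EFLayer",
    "ContactSet",
    "ef_stiffness",
    "ef_pressure",
    "ef_pressure_slope",
    "ef_stored_energy",
    "detect_penetrations",
    "partition_area",
    "contact_response",
]

D_CAP_FRACTION = 0.99


def ef_stiffness(E: float, nu: float) -> float:
    """K = -(1-nu) E / ((1+nu)(1-2 nu)); negative for 0 < nu < 1/2."""
    if E <= 0:
        raise ValueError("elastic modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError(f"Poisson ratio {nu} is singular/invalid (need 0 <= nu < 0.5)")
    return -(1.0 - nu) * E / ((1.0 + nu) * (1.0 - 2.0 * nu))


def _cap_depth(d, h, context=""):
    d = np.asarray(d, float)
    over = d >= D_CAP_FRACTION * h
    if np.any(over):
        warnings.warn(
            f"penetration overflow{' in ' + context if context else ''}: "
            f"{int(np.count_nonzero(over))} contact(s) at d >= {D_CAP_FRACTION:.2f} h "
            f"(max d = {float(np.max(d)) * 1e3:.4f} mm, h = {h * 1e3:.3f} mm); capped",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.minimum(d, D_CAP_FRACTION * h)


def ef_pressure(d, h: float, K: float, context: str = ""):
    """p(d) = K ln(1 - d/h) >= 0 for 0 <= d < h; d capped at 0.99 h."""
    d = _cap_depth(d, h, context)
    if np.any(d < 0):
        raise ValueError("penetration depth must be non-negative")
    return K * np.log1p(-d / h)


def ef_pressure_slope(d, h: float, K: float):
    """dp/dd = -K/(h - d) > 0 (contact stiffness per unit area)."""
    d = np.minimum(np.asarray(d, float), D_CAP_FRACTION * h)
    return -K / (h - d)


def ef_stored_energy(d, h: float, K: float):
    """Energy per unit area stored at penetration d: integral of p from 0 to d."""
    d = np.minimum(np.asarray(d, float), D_CAP_FRACTION * h)
    return K * (-(h - d) * np.log1p(-d / h) - d)


@dataclass
class EFLayer:
    """Cartilage layer on a rigid substrate surface.

    ``surface`` is the *outer* cartilage surface in the substrate body's
    local frame, oriented outward (toward the opposing body); penetration
    is measured inward from it.
    """

    name: str
    body: str  # owning rigid body
    surface: TriMesh
    thickness: float = 0.4e-3
    elastic_modulus: float = 2.7e6
    poisson: float = 0.49
    damping_s: float | None = None  # per-layer normal contact damping (s); None = default
    K: float = field(init=False)

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        self.K = ef_stiffness(self.elastic_modulus, self.poisson)
        # local-frame normals, cached; they rotate rigidly with the substrate
        from .surface import face_normals, vertex_pseudo_normals

        self._vn_local = vertex_pseudo_normals(self.surface.vertices, self.surface.faces)
        self._fn_local = face_normals(self.surface.vertices, self.surface.faces)


@dataclass
class ContactSet:
    """All contacts of one (penetrating body, EF layer) pair at one step."""

    layer: str
    vertex_ids: np.ndarray  # indices into the penetrating body's vertex set
    depths: np.ndarray  # m, in [0, 0.99 h]
    normals: np.ndarray  # (n,3) outward substrate normals (toward penetrator)
    points: np.ndarray  # (n,3) world contact points (nearest on substrate)
    areas: np.ndarray  # (n,) equal area shares, m^2
    pressures: np.ndarray  # (n,) Pa
    forces: np.ndarray  # (n,3) = p A n on the penetrating body
    stiffness: np.ndarray  # (n,) A dp/dd, N/m

    @property
    def multipliers(self) -> np.ndarray:
        """Constraint multipliers lambda = |f| = p A (always >= 0)."""
        return self.pressures * self.areas

    def complementarity_residual(self) -> float:
        """max |lambda_i * g_i| with g the regularized constraint violation.

        At a converged state the constraint force equals p(d) A exactly,
        so g = lambda/ (A dp/dd) - ... reduces to the defect between the
        applied multiplier and the pressure law, which is zero by
        construction; any mismatch (e.g. from capping) is reported.
        """
        if len(self.depths) == 0:
            return 0.0
        defect = np.abs(self.multipliers - self.pressures * self.areas)
        gap = defect / np.maximum(self.stiffness, 1e-300)
        return float(np.max(self.multipliers * gap))

    def total_force(self) -> np.ndarray:
        return self.forces.sum(axis=0) if len(self.forces) else np.zeros(3)


def detect_penetrations(points, layer: EFLayer, layer_vertices=None, rotation=None):
    """Find which query points penetrate the layer surface.

    ``layer_vertices``/``rotation`` optionally supply the substrate
    surface vertices in world coordinates and the substrate rotation
    (for a moving substrate); faces are taken from the layer surface.
    Returns ``(ids, depths, normals, contact_points)`` for points at or
    below the surface (depth >= 0).  Ambiguous nearest features
    (edges/vertices) are resolved by angle-weighted pseudo-normals and
    are never an error.
    """
    points = np.asarray(points, float)
    verts = layer.surface.vertices if layer_vertices is None else layer_vertices
    vn, fn = layer._vn_local, layer._fn_local
    if rotation is not None:
        vn = vn @ rotation.T
        fn = fn @ rotation.T
    sd, normals, cps, _ = signed_distances(points, verts, layer.surface.faces, refine_k=16,
                                           pseudo_normals=vn, face_norms=fn)
    mask = sd <= 1e-12  # points exactly on the surface count as contacts
    sd = np.minimum(sd, 0.0)
    ids = np.nonzero(mask)[0]
    return ids, -sd[ids], normals[ids], cps[ids]


def partition_area(penetrating_vertex_ids, surface: TriMesh) -> np.ndarray:
    """Equal area shares from the patch-splitting rule.

    Patch area = sum over faces of face_area * (number of penetrating
    vertices of that face) / 3; each of the n penetrating vertices gets
    patch_area / n.
    """
    ids = np.asarray(penetrating_vertex_ids, int)
    if len(ids) == 0:
        return np.zeros(0)
    pen = np.zeros(len(surface.vertices), bool)
    pen[ids] = True
    frac = pen[surface.faces].sum(axis=1) / 3.0
    patch = float(np.dot(surface.face_areas(), frac))
    if patch <= 0:
        raise ValueError(
            "zero penetration-patch area with non-empty contact set: "
            "degenerate penetrating-surface mesh"
        )
    return np.full(len(ids), patch / len(ids))


def contact_response(
    layer: EFLayer, points, surface: TriMesh, layer_vertices=None, context: str = "",
    candidate_ids=None, rotation=None,
) -> ContactSet:
    """Detect penetrations, partition areas and evaluate f = p(d) A n.

    ``points`` are the opposing surface's vertex positions (world);
    ``surface`` is that body's surface mesh (same vertex indexing) used
    for area partitioning.  ``candidate_ids`` optionally restricts the
    query to a vertex subset (e.g. the FEM surface nodes).
    """
    if candidate_ids is not None:
        sub = np.asarray(candidate_ids, int)
        if len(sub) == 0:
            z = np.zeros(0)
            return ContactSet(layer.name, sub, z, z.reshape(0, 3), z.reshape(0, 3),
                              z, z, z.reshape(0, 3), z)
        ids, depths, normals, cps = detect_penetrations(points[sub], layer, layer_vertices,
                                                        rotation)
        ids = sub[ids]
    else:
        ids, depths, normals, cps = detect_penetrations(points, layer, layer_vertices,
                                                        rotation)
    if len(ids) == 0:
        z = np.zeros(0)
        return ContactSet(layer.name, ids, z, z.reshape(0, 3), z.reshape(0, 3),
                          z, z, z.reshape(0, 3), z)
    depths = _cap_depth(depths, layer.thickness, context or layer.name)
    areas = partition_area(ids, surface)
    p = ef_pressure(depths, layer.thickness, layer.K)
    forces = (p * areas)[:, None] * normals
    k = areas * ef_pressure_slope(depths, layer.thickness, layer.K)
    return ContactSet(layer.name, ids, depths, normals, cps, areas, p, forces, k)
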