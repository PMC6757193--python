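"""Assembly of the coupled jaw system.

A :class:`JawSystem` holds the rigid bodies (dynamic mandible, static
skull and hyoid), the FEM disks, the Hill muscles, the capsule
ligaments, the elastic-foundation cartilage layers and the contact
pairs.  It owns the degree-of-freedom layout (mandible twist first,
then each disk's nodal velocities) and assembles the generalized mass,
damping, stiffness and force terms that the implicit integrator
consumes.

Coupling conventions: contact, ligament and muscle elements
contribute (a) equal-and-opposite force pairs and (b) implicit
stiffness/damping along their lines of action, built from sparse rows
g mapping the dof vector to relative rates, as K += k g^T g (muscle
force-velocity slope and length/geometric stiffness included; only the
small gyroscopic torque stays explicit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .actuators import DistributedAttachment, HillMuscle, LigamentCable, \
    hill_force_and_slope, hill_length_stiffness, ligament_tension, wrap_path
from .ef_contact import ContactSet, EFLayer, contact_response, ef_stored_energy, \
    partition_area
from .fem import FemBody
from .mesh_io import TriMesh
from .rigid_body import RigidBody, cross3

__all__ = ["ContactPair", "ContactConstraint", "Landmark", "JawSystem"]


@dataclass
class ContactConstraint:
    """One linearized unilateral contact constraint, anchored at the
    start-of-step state.

    ``cols``/``vals`` form the sparse row g mapping dof velocities to the
    separation rate along the contact normal (positive = separating);
    the force on the system dofs is lambda * vals at cols.  ``depth`` is
    the signed penetration at the anchor state (negative = gap),
    ``lam0`` the anchored force magnitude (p(d0) A for penetrating
    contacts, k d0 <= 0 for anticipated ones) and ``k`` the compliance
    slope A dp/dd.
    """

    pair: tuple
    vertex_id: int
    cols: np.ndarray
    vals: np.ndarray
    k: float
    lam0: float
    depth: float
    area: float
    normal: np.ndarray
    point: np.ndarray
    thickness: float = 0.0  # layer h, for end-of-step re-anchoring
    K_law: float = 0.0  # foundation stiffness K of the layer
    damping_s: float | None = None  # layer-specific normal damping override
    t_rows: list | None = None  # two tangential (cols, vals) rows for shear damping

    def law(self, d):
        """(lambda, k) of the foundation law at depth d (d < 0 = gap)."""
        from .ef_contact import ef_pressure, ef_pressure_slope

        d = min(d, 0.99 * self.thickness)
        k_at = float(self.area * ef_pressure_slope(max(d, 0.0), self.thickness,
                                                   self.K_law))
        if d > 0:
            lam = float(ef_pressure(d, self.thickness, self.K_law) * self.area)
        else:
            lam = k_at * d
        return lam, k_at


@dataclass
class ContactPair:
    """One (penetrating surface, EF layer) pairing.

    ``penetrator`` names a FemBody (kind='fem': its surface nodes are
    the query points) or a RigidBody (kind='rigid': the vertices of
    ``rigid_mesh``, a local-frame TriMesh, are the query points).
    ``candidates`` caches the vertex subset that can plausibly contact
    the layer (those whose outward normal opposes the layer normal in
    the reference configuration).
    """

    penetrator: str
    layer: str
    kind: str = "fem"
    rigid_mesh: TriMesh | None = None
    candidates: np.ndarray | None = None


@dataclass
class Landmark:
    body: str
    point: np.ndarray  # local frame


class JawSystem:
    def __init__(self, gravity=(0.0, 0.0, -9.81)):
        self.bodies: dict[str, RigidBody] = {}
        self.fem_bodies: dict[str, FemBody] = {}
        self.muscles: list[HillMuscle] = []
        self.ligaments: list[LigamentCable] = []
        self.ef_layers: dict[str, EFLayer] = {}
        self.contact_pairs: list[ContactPair] = []
        self.landmarks: dict[str, Landmark] = {}
        self.gravity = np.asarray(gravity, float)
        self.linear_drag = 50.0  # N s/m on the mandible
        self.angular_drag = 0.3  # N m s/rad
        self.fem_damping_beta = 2e-3  # stiffness-proportional, s
        self._dof_slices: dict[str, slice] = {}
        self._n_dof = 0
        self._K_fem_cache: dict[str, sp.csr_matrix] = {}

    # ------------------------------------------------------------ assembly
    def add_body(self, body: RigidBody):
        self.bodies[body.name] = body
        return body

    def add_fem_body(self, fb: FemBody):
        self.fem_bodies[fb.name] = fb
        return fb

    def add_layer(self, layer: EFLayer):
        if layer.body not in self.bodies:
            raise KeyError(f"EF layer {layer.name!r} references unknown body {layer.body!r}")
        self.ef_layers[layer.name] = layer
        return layer

    def finalize(self):
        """Freeze the dof layout: disk nodal dofs first, rigid twists last.

        The rigid-body dofs couple densely to every contact; placing them
        last keeps sparse-factorization fill-in local.
        """
        self._dof_slices = {}
        off = 0
        for name, fb in self.fem_bodies.items():
            self._dof_slices[name] = slice(off, off + 3 * len(fb.positions))
            off += 3 * len(fb.positions)
        for name, b in self.bodies.items():
            if b.dynamic:
                self._dof_slices[name] = slice(off, off + 6)
                off += 6
        self._n_dof = off
        for m in self.muscles:
            if m.l_opt is None:
                m.l_opt = self._muscle_length(m)
        self._K_fem_cache.clear()

    @property
    def n_dof(self) -> int:
        return self._n_dof

    def dof_slice(self, name: str) -> slice:
        return self._dof_slices[name]

    # ------------------------------------------------------------ state I/O
    def get_velocities(self) -> np.ndarray:
        v = np.zeros(self._n_dof)
        for name, sl in self._dof_slices.items():
            if name in self.bodies:
                b = self.bodies[name]
                v[sl] = np.concatenate([b.velocity, b.omega])
            else:
                v[sl] = self.fem_bodies[name].velocities.ravel()
        return v

    def set_velocities(self, v: np.ndarray):
        for name, sl in self._dof_slices.items():
            if name in self.bodies:
                self.bodies[name].velocity = v[sl][:3].copy()
                self.bodies[name].omega = v[sl][3:].copy()
            else:
                fb = self.fem_bodies[name]
                fb.velocities = v[sl].reshape(-1, 3).copy()

    def snapshot(self):
        snap = {}
        for name, b in self.bodies.items():
            snap[name] = (b.position.copy(), b.quaternion.copy(), b.velocity.copy(),
                          b.omega.copy())
        for name, fb in self.fem_bodies.items():
            snap[name] = (fb.positions.copy(), fb.velocities.copy())
        return snap

    def restore(self, snap):
        for name, b in self.bodies.items():
            b.position, b.quaternion, b.velocity, b.omega = (a.copy() for a in snap[name])
        for name, fb in self.fem_bodies.items():
            fb.positions, fb.velocities = (a.copy() for a in snap[name])

    def advance_positions(self, dt: float, v: np.ndarray):
        """Advance poses/nodes with the given dof velocities (in place)."""
        self.set_velocities(v)
        for b in self.bodies.values():
            if b.dynamic:
                b.advance(dt)
        for fb in self.fem_bodies.values():
            fb.positions = fb.positions + dt * fb.velocities

    # ------------------------------------------------------------ mass
    def mass_matrix(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for name, sl in self._dof_slices.items():
            if name in self.bodies:
                b = self.bodies[name]
                o = sl.start
                for k in range(3):
                    rows.append(o + k); cols.append(o + k); vals.append(b.mass)
                Iw = b.world_inertia()
                for i in range(3):
                    for j in range(3):
                        rows.append(o + 3 + i); cols.append(o + 3 + j); vals.append(Iw[i, j])
            else:
                fb = self.fem_bodies[name]
                m3 = np.repeat(fb.node_mass, 3)
                idx = np.arange(sl.start, sl.stop)
                rows.extend(idx); cols.extend(idx); vals.extend(m3)
        return sp.coo_matrix((vals, (rows, cols)), shape=(self._n_dof, self._n_dof)).tocsr()

    # ------------------------------------------------------------ helpers
    def _point_row(self, body_name: str, world_point: np.ndarray, direction: np.ndarray):
        """Sparse row (cols, vals) mapping dofs to direction . point-velocity."""
        if body_name in self.bodies:
            b = self.bodies[body_name]
            if not b.dynamic:
                return np.empty(0, int), np.empty(0)
            J = b.point_jacobian(world_point)  # 3x6
            sl = self._dof_slices[body_name]
            return np.arange(sl.start, sl.stop), direction @ J
        raise KeyError(body_name)

    def _attachment_row(self, end, positions_of, direction):
        """Row for a ligament end (rigid point or distributed FEM anchor)."""
        if isinstance(end, DistributedAttachment):
            fb = self.fem_bodies[end.body]
            sl = self._dof_slices[end.body]
            cols = (sl.start + 3 * end.node_ids[:, None] + np.arange(3)[None, :]).ravel()
            vals = np.outer(end.weights, direction).ravel()
            return cols, vals
        body_name, local = end
        world = self.bodies[body_name].world_point(local)
        return self._point_row(body_name, world, direction)

    def _end_point(self, end) -> np.ndarray:
        if isinstance(end, DistributedAttachment):
            return end.point(self.fem_bodies[end.body].positions)
        body_name, local = end
        return self.bodies[body_name].world_point(local)

    def _end_velocity(self, end) -> np.ndarray:
        if isinstance(end, DistributedAttachment):
            return end.weights @ self.fem_bodies[end.body].velocities[end.node_ids]
        body_name, local = end
        return self.bodies[body_name].point_velocity(local)

    def _apply_force_at(self, f_vec, body_name, world_point, force):
        """Accumulate a world force at a world point onto a body's dofs."""
        if body_name in self.bodies:
            b = self.bodies[body_name]
            if not b.dynamic:
                return
            sl = self._dof_slices[body_name]
            f_vec[sl.start : sl.start + 3] += force
            r = world_point - b.position
            f_vec[sl.start + 3 : sl.start + 6] += cross3(r, force)
        else:
            raise KeyError(body_name)

    def _muscle_length(self, m: HillMuscle) -> float:
        p0 = self.bodies[m.origin_body].world_point(m.origin_point)
        p1 = self.bodies[m.insertion_body].world_point(m.insertion_point)
        return float(np.linalg.norm(p1 - p0))

    # ------------------------------------------------------------ forces
    def evaluate(self, activations: dict[str, float], with_stiffness: bool = True,
                 fem_tangent: dict[str, sp.csr_matrix] | None = None,
                 include_contacts: bool = True):
        """Forces, damping and stiffness at the current state.

        Returns ``(f, D, K, contact_sets)``: total generalized forces
        (including damping forces at the current velocities), the
        velocity Jacobian D = -df/dv, the position stiffness
        K = -df/dx (contact/ligament/FEM terms) and the per-pair
        contact sets.  With ``with_stiffness=False`` only forces and
        contacts are computed (diagnostics; Rayleigh damping forces are
        then omitted since they need the cached FEM tangent).
        ``fem_tangent`` optionally supplies cached FEM tangents.
        """
        n = self._n_dof
        f = np.zeros(n)
        Drows, Dcols, Dvals = [], [], []
        Krows, Kcols, Kvals = [], [], []

        def add_outer(cols, vals, k, R, C, V):
            if len(cols) == 0 or k == 0.0:
                return
            R.append(np.repeat(cols, len(cols)))
            C.append(np.tile(cols, len(cols)))
            V.append(k * np.outer(vals, vals).ravel())

        # gravity + drag + gyroscopics on rigid bodies
        for name, b in self.bodies.items():
            if not b.dynamic:
                continue
            sl = self._dof_slices[name]
            f[sl.start : sl.start + 3] += b.mass * self.gravity - self.linear_drag * b.velocity
            f[sl.start + 3 : sl.start + 6] += (
                -cross3(b.omega, b.world_inertia() @ b.omega) - self.angular_drag * b.omega
            )
            idx = np.arange(sl.start, sl.stop)
            Drows.append(idx); Dcols.append(idx)
            Dvals.append(np.array([self.linear_drag] * 3 + [self.angular_drag] * 3))

        # gravity + Rayleigh damping on FEM disks; internal forces/tangent
        K_fem_global = None
        for name, fb in self.fem_bodies.items():
            sl = self._dof_slices[name]
            f[sl] += (fb.node_mass[:, None] * self.gravity).ravel()
            f[sl] += fb.internal_forces().ravel()
        if with_stiffness and self.fem_bodies:
            cache = fem_tangent if fem_tangent is not None else {}
            rebuilt = False
            for name, fb in self.fem_bodies.items():
                if name not in cache:
                    cache[name] = fb.tangent_stiffness()
                    rebuilt = True
            if rebuilt or "_global" not in cache:
                rows, cols, vals = [], [], []
                for name in self.fem_bodies:
                    Kf = cache[name].tocoo()
                    sl = self._dof_slices[name]
                    rows.append(Kf.row + sl.start); cols.append(Kf.col + sl.start)
                    vals.append(Kf.data)
                cache["_global"] = sp.coo_matrix(
                    (np.concatenate(vals),
                     (np.concatenate(rows), np.concatenate(cols))),
                    shape=(n, n),
                ).tocsr()
            K_fem_global = cache["_global"]
            # stiffness-proportional (Rayleigh) damping force on the disks
            v_fem = np.zeros(n)
            for name, fb in self.fem_bodies.items():
                v_fem[self._dof_slices[name]] = fb.velocities.ravel()
            f -= self.fem_damping_beta * (K_fem_global @ v_fem)

        # muscles
        for m in self.muscles:
            p0 = self.bodies[m.origin_body].world_point(m.origin_point)
            p1 = self.bodies[m.insertion_body].world_point(m.insertion_point)
            d = p1 - p0
            L = np.linalg.norm(d)
            u = d / L
            v_rel = self._end_velocity((m.insertion_body, m.insertion_point)) - \
                self._end_velocity((m.origin_body, m.origin_point))
            ldot = float(u @ v_rel)
            a = activations.get(m.name, 0.0)
            T, dT_dv = hill_force_and_slope(m, L, ldot, a)
            self._apply_force_at(f, m.insertion_body, p1, -T * u)
            self._apply_force_at(f, m.origin_body, p0, +T * u)
            if with_stiffness:
                def rel_row(direction):
                    ci, vi = self._point_row(m.insertion_body, p1, direction) if \
                        self.bodies[m.insertion_body].dynamic \
                        else (np.empty(0, int), np.empty(0))
                    co, vo = self._point_row(m.origin_body, p0, direction) if \
                        self.bodies[m.origin_body].dynamic \
                        else (np.empty(0, int), np.empty(0))
                    return np.concatenate([ci, co]), np.concatenate([vi, -vo])

                cols, vals = rel_row(u)
                add_outer(cols, vals, dT_dv, Drows, Dcols, Dvals)
                # implicit muscle position stiffness: length stiffness along
                # the line of action plus the geometric (transverse) term
                k_len = hill_length_stiffness(m, L, ldot, a)
                add_outer(cols, vals, k_len, Krows, Kcols, Kvals)
                t1 = np.cross(u, [0.0, 0.0, 1.0])
                if np.linalg.norm(t1) < 1e-6:
                    t1 = np.cross(u, [0.0, 1.0, 0.0])
                t1 /= np.linalg.norm(t1)
                t2 = np.cross(u, t1)
                k_geo = T / L
                for tdir in (t1, t2):
                    ct, vt = rel_row(tdir)
                    add_outer(ct, vt, k_geo, Krows, Kcols, Kvals)

        # ligaments
        lig_energy = 0.0
        for lig in self.ligaments:
            pA = self._end_point(lig.end_a)
            pB = self._end_point(lig.end_b)
            if lig.wrap is not None:
                wb = self.bodies[lig.wrap.body]
                cyl_p = wb.world_point(lig.wrap.point)
                cyl_u = wb.rotation @ lig.wrap.axis
                try:
                    L, via = wrap_path(pA, pB, cyl_p, cyl_u, lig.wrap.radius)
                except ValueError:
                    # endpoint transiently inside the cylinder: degrade to a
                    # straight cable rather than aborting the step
                    import warnings as _w

                    _w.warn(f"ligament {lig.name!r}: endpoint inside wrap cylinder; "
                            "using straight path this step", RuntimeWarning, stacklevel=2)
                    L, via = float(np.linalg.norm(pB - pA)), np.empty((0, 3))
            else:
                L, via = float(np.linalg.norm(pB - pA)), np.empty((0, 3))
            T = ligament_tension(lig, L)
            # direction of pull at each end (first/last path segment)
            qA = via[0] if len(via) else pB
            qB = via[-1] if len(via) else pA
            uA = (qA - pA) / max(np.linalg.norm(qA - pA), 1e-12)
            uB = (qB - pB) / max(np.linalg.norm(qB - pB), 1e-12)
            if T > 0.0:
                lig_energy += 0.5 * lig.k_eff * (L - lig.slack_length) ** 2
                fA, fB = T * uA, T * uB
                self._apply_end_force(f, lig.end_a, pA, fA)
                self._apply_end_force(f, lig.end_b, pB, fB)
                if len(via) and self.bodies[lig.wrap.body].dynamic:
                    mid = via[len(via) // 2]
                    self._apply_force_at(f, lig.wrap.body, mid, -(fA + fB))
            if with_stiffness and T >= 0.0 and L >= lig.slack_length:
                cA, vA = self._attachment_row(lig.end_a, None, uA)
                cB, vB = self._attachment_row(lig.end_b, None, uB)
                cols = np.concatenate([cA, cB]); vals = np.concatenate([vA, vB])
                add_outer(cols, vals, lig.k_eff, Krows, Kcols, Kvals)

        # contacts
        contact_sets: dict[tuple[str, str], ContactSet] = {}
        for pair in self.contact_pairs if include_contacts else []:
            layer = self.ef_layers[pair.layer]
            sub_body = self.bodies[layer.body]
            sub_rot = sub_body.rotation
            layer_world = layer.surface.vertices @ sub_rot.T + sub_body.position
            if pair.kind == "fem":
                fb = self.fem_bodies[pair.penetrator]
                pts = fb.positions
                surf = fb.world_surface()
                if pair.candidates is None:
                    pair.candidates = self._facing_candidates(fb, layer, layer_world,
                                                              sub_rot)
                base = pair.candidates
                cand = self._aabb_candidates(pts[base], layer_world)
                cs = contact_response(layer, pts, surf, layer_vertices=layer_world,
                                      context=f"{pair.penetrator}/{pair.layer}",
                                      candidate_ids=base[cand],
                                      rotation=sub_rot)
            else:
                pen_body = self.bodies[pair.penetrator]
                world_mesh = pen_body.world_mesh(pair.rigid_mesh)
                cand = self._aabb_candidates(world_mesh.vertices, layer_world)
                cs = contact_response(layer, world_mesh.vertices, world_mesh,
                                      layer_vertices=layer_world,
                                      context=f"{pair.penetrator}/{pair.layer}",
                                      candidate_ids=cand, rotation=sub_rot)
            contact_sets[(pair.penetrator, pair.layer)] = cs
            for i in range(len(cs.vertex_ids)):
                force, nrm, cp, kc = cs.forces[i], cs.normals[i], cs.points[i], cs.stiffness[i]
                if pair.kind == "fem":
                    sl = self._dof_slices[pair.penetrator]
                    nid = cs.vertex_ids[i]
                    f[sl.start + 3 * nid : sl.start + 3 * nid + 3] += force
                    c_pen = np.arange(sl.start + 3 * nid, sl.start + 3 * nid + 3)
                    v_pen = nrm
                else:
                    self._apply_force_at(f, pair.penetrator, cp, force)
                    c_pen, v_pen = self._point_row(pair.penetrator, cp, nrm) if \
                        self.bodies[pair.penetrator].dynamic else (np.empty(0, int), np.empty(0))
                if sub_body.dynamic:
                    self._apply_force_at(f, layer.body, cp, -force)
                    c_sub, v_sub = self._point_row(layer.body, cp, nrm)
                else:
                    c_sub, v_sub = np.empty(0, int), np.empty(0)
                if with_stiffness:
                    cols = np.concatenate([c_pen, c_sub])
                    vals = np.concatenate([v_pen, -v_sub])
                    add_outer(cols, vals, kc, Krows, Kcols, Kvals)

        def build(R, C, V):
            if not R:
                return sp.csr_matrix((n, n))
            return sp.coo_matrix(
                (np.concatenate(V), (np.concatenate(R), np.concatenate(C))), shape=(n, n)
            ).tocsr()

        D = build(Drows, Dcols, Dvals)
        K = build(Krows, Kcols, Kvals)
        if K_fem_global is not None:
            K = K + K_fem_global
            D = D + self.fem_damping_beta * K_fem_global
        self._last_ligament_energy = lig_energy
        return f, D, K, contact_sets

    # ------------------------------------------------------- contact constraints
    def contact_constraints(self, margin: float = 4e-4) -> list[ContactConstraint]:
        """Linearized unilateral contact constraints at the current state.

        Detects every candidate vertex within ``margin`` of each EF
        layer (on the penetrating side of grazing) and builds, per
        vertex, the separation-rate row g, the anchored force lam0 and
        the compliance slope k.  Penetrating vertices use the equal
        area-split rule; anticipated (gap) vertices use their incident
        surface-area share, since the penetration patch does not contain
        them yet.
        """
        from .ef_contact import ef_pressure, ef_pressure_slope
        from .surface import signed_distances

        out: list[ContactConstraint] = []
        for pair in self.contact_pairs:
            layer = self.ef_layers[pair.layer]
            sub_body = self.bodies[layer.body]
            sub_rot = sub_body.rotation
            layer_world = layer.surface.vertices @ sub_rot.T + sub_body.position
            if pair.kind == "fem":
                fb = self.fem_bodies[pair.penetrator]
                if pair.candidates is None:
                    pair.candidates = self._facing_candidates(fb, layer, layer_world,
                                                              sub_rot)
                base = pair.candidates
                pts_all = fb.positions
                surf = fb.world_surface()
            else:
                pen_body = self.bodies[pair.penetrator]
                surf = pen_body.world_mesh(pair.rigid_mesh)
                pts_all = surf.vertices
                base = np.arange(len(pts_all))
            cand = base[self._aabb_candidates(pts_all[base], layer_world, margin=2e-3)]
            if len(cand) == 0:
                continue
            vn = layer._vn_local @ sub_rot.T
            fn = layer._fn_local @ sub_rot.T
            sd, normals, cps, _ = signed_distances(
                pts_all[cand], layer_world, layer.surface.faces, refine_k=16,
                pseudo_normals=vn, face_norms=fn)
            near = sd <= margin
            if not np.any(near):
                continue
            ids = cand[near]
            d0 = -sd[near]  # positive = penetration
            nrm = normals[near]
            cp = cps[near]
            # the solver uses per-vertex incident areas: they are constant
            # in time, so the regularized forces are continuous (the
            # patch/n equal-split rule of the reported contact sets jumps
            # whenever the penetrating count changes, which would shake
            # the lightly damped joint rocking mode every step)
            incident = self._incident_vertex_areas(surf)
            areas = incident[ids]
            h, Kp = layer.thickness, layer.K
            dpen = np.minimum(d0, 0.99 * h)
            kvec = areas * (-Kp) / (h - np.maximum(dpen, 0.0))
            lamvec = np.where(dpen > 0, Kp * np.log1p(-np.maximum(dpen, 0.0) / h) * areas,
                              kvec * dpen)
            for j in range(len(ids)):
                # relative-velocity rows along the normal and two tangents:
                # direction . v_penetrator - direction . v_substrate
                nj = nrm[j]
                t1 = np.cross(nj, [0.0, 0.0, 1.0])
                if np.linalg.norm(t1) < 1e-6:
                    t1 = np.cross(nj, [0.0, 1.0, 0.0])
                t1 = t1 / np.linalg.norm(t1)
                t2 = np.cross(nj, t1)

                def rel_row(direction):
                    if pair.kind == "fem":
                        sl = self._dof_slices[pair.penetrator]
                        c_pen = np.arange(sl.start + 3 * ids[j],
                                          sl.start + 3 * ids[j] + 3)
                        v_pen = direction
                    else:
                        c_pen, v_pen = (self._point_row(pair.penetrator, cp[j], direction)
                                        if self.bodies[pair.penetrator].dynamic
                                        else (np.empty(0, int), np.empty(0)))
                    if sub_body.dynamic:
                        c_sub, v_sub = self._point_row(layer.body, cp[j], direction)
                    else:
                        c_sub, v_sub = np.empty(0, int), np.empty(0)
                    return (np.concatenate([c_pen, c_sub]),
                            np.concatenate([v_pen, -v_sub]))

                cols, vals = rel_row(nj)
                out.append(ContactConstraint(
                    pair=(pair.penetrator, pair.layer), vertex_id=int(ids[j]),
                    cols=cols, vals=vals, k=float(kvec[j]), lam0=float(lamvec[j]),
                    depth=float(d0[j]), area=float(areas[j]), normal=nj.copy(),
                    point=cp[j].copy(), thickness=h, K_law=Kp,
                    damping_s=layer.damping_s,
                    t_rows=[rel_row(t1), rel_row(t2)]))
        return out

    @staticmethod
    def _incident_vertex_areas(surface: TriMesh) -> np.ndarray:
        a = np.zeros(len(surface.vertices))
        fa = surface.face_areas() / 3.0
        for k in range(3):
            np.add.at(a, surface.faces[:, k], fa)
        return a

    @staticmethod
    def _facing_candidates(fb, layer, layer_world, rotation, dot_max=0.3):
        """Surface nodes whose outward normal opposes the layer's (reference)."""
        from .surface import signed_distances, vertex_pseudo_normals

        node_n = vertex_pseudo_normals(fb.positions, fb.surface.faces)
        vn = layer._vn_local @ rotation.T
        fn = layer._fn_local @ rotation.T
        _, layer_n, _, _ = signed_distances(
            fb.positions[fb.surface_nodes], layer_world, layer.surface.faces,
            refine_k=16, pseudo_normals=vn, face_norms=fn)
        dots = np.einsum("ij,ij->i", node_n[fb.surface_nodes], layer_n)
        return fb.surface_nodes[dots < dot_max]

    @staticmethod
    def _aabb_candidates(points, layer_vertices, margin=2e-3):
        lo = layer_vertices.min(axis=0) - margin
        hi = layer_vertices.max(axis=0) + margin
        return np.nonzero(np.all((points >= lo) & (points <= hi), axis=1))[0]

    def _apply_end_force(self, f_vec, end, world_point, force):
        if isinstance(end, DistributedAttachment):
            fb = self.fem_bodies[end.body]
            sl = self._dof_slices[end.body]
            nodal = end.distribute(force)
            idx = (sl.start + 3 * end.node_ids[:, None] + np.arange(3)[None, :])
            np.add.at(f_vec, idx.ravel(), nodal.ravel())
        else:
            body_name, local = end
            self._apply_force_at(f_vec, body_name, self.bodies[body_name].world_point(local),
                                 force)

    # ------------------------------------------------------------ energies
    def energies(self, contact_sets=None) -> dict[str, float]:
        kin = sum(b.kinetic_energy() for b in self.bodies.values())
        for fb in self.fem_bodies.values():
            kin += 0.5 * float(np.sum(fb.node_mass[:, None] * fb.velocities**2))
        strain = sum(fb.strain_energy() for fb in self.fem_bodies.values())
        lig = 0.0
        for l in self.ligaments:
            pA, pB = self._end_point(l.end_a), self._end_point(l.end_b)
            if l.wrap is not None:
                wb = self.bodies[l.wrap.body]
                L, _ = wrap_path(pA, pB, wb.world_point(l.wrap.point),
                                 wb.rotation @ l.wrap.axis, l.wrap.radius)
            else:
                L = float(np.linalg.norm(pB - pA))
            if L > l.slack_length:
                lig += 0.5 * l.k_eff * (L - l.slack_length) ** 2
        ef = 0.0
        if contact_sets:
            for cs in contact_sets.values():
                layer = self.ef_layers[cs.layer]
                if len(cs.depths):
                    ef += float(np.sum(cs.areas * ef_stored_energy(
                        cs.depths, layer.thickness, layer.K)))
        return {
            "kinetic": kin, "strain": strain, "ligament": lig, "ef_stored": ef,
            "total": kin + strain + lig + ef,
        }
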