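"""Hill-type muscles and capsule ligament cables.

Muscles are point-to-point actuators: tension =
f_max [a fl(lhat) fv(vhat) + fp(lhat)] + damping, clamped non-negative
(muscles only pull).  Activation is a prescribed signal in [0, 1]; no
excitation-to-activation dynamics are modelled.

Curve shapes (per-muscle overridable):
  fl  Gaussian exp(-((lhat-1)/0.45)^2), normalized fl(1)=1
  fv  Hill hyperbola, a/f0 = 0.25, v_max = 10 l_opt/s; zero at maximal
      shortening speed, mild eccentric plateau capped at 1.4
  fp  exponential toe from lhat = 1 reaching f_max at lhat = 1.6

Ligaments are slack cables: zero tension up to the slack length, then
linear with k_eff = modulus * area / slack_length (modulus 250 MPa,
nominal 1 mm^2 cross-section).  The anterior capsule ligament wraps a
cylinder at the condyle; attachments on the FEM disk are distributed
over ~20 surface nodes with inverse-distance convex weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HillCurves",
    "HillMuscle",
    "WrapCylinder",
    "LigamentCable",
    "DistributedAttachment",
    "hill_force",
    "wrap_path",
    "ligament_tension",
    "build_distributed_attachment",
]


@dataclass(frozen=True)
class HillCurves:
    fl_width: float = 0.45
    fv_shape: float = 0.25  # a / f0 of the Hill hyperbola
    v_max_per_lopt: float = 10.0  # maximal shortening velocity, l_opt / s
    fp_toe_exponent: float = 5.0
    fp_limit_stretch: float = 1.6  # fp reaches 1 here
    ecc_plateau: float = 1.4

    def fl(self, lhat):
        return np.exp(-(((lhat - 1.0) / self.fl_width) ** 2))

    def fv(self, vhat):
        """vhat = (d length/dt) / v_max; negative = shortening."""
        vhat = np.asarray(vhat, float)
        a = self.fv_shape
        conc = np.clip((1.0 + vhat) / (1.0 - vhat / a), 0.0, 1.0)
        ecc = self.ecc_plateau - (self.ecc_plateau - 1.0) * np.exp(-vhat / a)
        return np.where(vhat < 0, conc, ecc)

    def fp(self, lhat):
        lhat = np.asarray(lhat, float)
        k = self.fp_toe_exponent
        span = self.fp_limit_stretch - 1.0
        raw = np.expm1(k * np.clip(lhat - 1.0, 0.0, None) / span) / np.expm1(k)
        return np.where(lhat > 1.0, raw, 0.0)

    def fv_slope(self, vhat):
        """d fv / d vhat (>= 0: force rises with lengthening rate)."""
        a = self.fv_shape
        if vhat < 0:
            return (1.0 + 1.0 / a) / (1.0 - vhat / a) ** 2 if vhat > -1.0 else 0.0
        return (self.ecc_plateau - 1.0) / a * np.exp(-vhat / a)


@dataclass
class HillMuscle:
    name: str
    origin_body: str
    origin_point: np.ndarray  # local, metres
    insertion_body: str
    insertion_point: np.ndarray
    f_max: float
    l_opt: float | None = None  # None: set to the initial path length
    damping: float | None = None  # N s/m; None: 0.01 f_max s / l_opt
    group: str = ""
    curves: HillCurves = field(default_factory=HillCurves)

    def resolved_damping(self) -> float:
        if self.damping is not None:
            return self.damping
        return 0.01 * self.f_max / self.l_opt  # seconds implied: 0.01 f_max s / l_opt


def hill_length_stiffness(muscle: HillMuscle, length: float, velocity: float,
                          activation: float) -> float:
    """dT/dL (N/m), clamped non-negative for use as implicit stiffness.

    The descending limb of the force-length curve has negative slope;
    only the stabilizing (positive) part enters the Jacobian.
    """
    c = muscle.curves
    lhat = length / muscle.l_opt
    v_max = c.v_max_per_lopt * muscle.l_opt
    vhat = velocity / v_max
    fl_slope = c.fl(lhat) * (-2.0 * (lhat - 1.0) / c.fl_width**2)
    k = c.fp_toe_exponent
    span = c.fp_limit_stretch - 1.0
    fp_slope = (k / span) * np.exp(k * max(lhat - 1.0, 0.0) / span) / np.expm1(k) \
        if lhat > 1.0 else 0.0
    dT_dlhat = muscle.f_max * (activation * fl_slope * c.fv(vhat) + fp_slope)
    return float(max(dT_dlhat / muscle.l_opt, 0.0))


def hill_force(muscle: HillMuscle, length: float, velocity: float, activation: float) -> float:
    """Scalar tension (N, >= 0). ``velocity`` is d length / dt (m/s)."""
    return hill_force_and_slope(muscle, length, velocity, activation)[0]


def hill_force_and_slope(muscle: HillMuscle, length: float, velocity: float,
                         activation: float) -> tuple[float, float]:
    """Tension and its velocity derivative dT/d(ldot) (N s/m, >= 0).

    The slope drives the implicit damping treatment: the force-velocity
    curve is steep (|dfv/dvhat| ~ 5 near isometric), so at high
    activation a muscle contributes damping of order f_max/v_max that an
    explicit integrator could not handle at dt = 1 ms.
    """
    if not (0.0 <= activation <= 1.0):
        raise ValueError(f"activation {activation} outside [0, 1]")
    if length <= 0:
        raise ValueError("muscle length must be positive")
    c = muscle.curves
    lhat = length / muscle.l_opt
    v_max = c.v_max_per_lopt * muscle.l_opt
    vhat = velocity / v_max
    afl = activation * c.fl(lhat)
    tension = muscle.f_max * (afl * c.fv(vhat) + c.fp(lhat)) \
        + muscle.resolved_damping() * velocity
    slope = muscle.f_max * afl * c.fv_slope(vhat) / v_max + muscle.resolved_damping()
    if tension <= 0.0:
        return 0.0, 0.0
    return float(tension), float(slope)


@dataclass
class WrapCylinder:
    """Infinite cylinder owned by a rigid body, in that body's local frame."""

    body: str
    point: np.ndarray  # a point on the axis
    axis: np.ndarray  # unit direction
    radius: float


def wrap_path(p0, p1, cylinder_point, cylinder_axis, radius):
    """Shortest path from p0 to p1 around an infinite cylinder.

    If the straight segment clears the cylinder (in the plane orthogonal
    to the axis) the path is the segment itself.  Otherwise the path is
    two tangent segments joined by a geodesic arc in the orthogonal
    plane, with the axial coordinate interpolated by path fraction.

    Returns ``(length, via_points)`` where via_points is an (n,3) array
    of intermediate points on the cylinder surface (empty if unwrapped).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    c = np.asarray(cylinder_point, float)
    u = np.asarray(cylinder_axis, float)
    u = u / np.linalg.norm(u)

    def decompose(p):
        d = p - c
        z = d @ u
        r = d - z * u
        return r, z

    r0, z0 = decompose(p0)
    r1, z1 = decompose(p1)
    rho0, rho1 = np.linalg.norm(r0), np.linalg.norm(r1)
    if rho0 <= radius or rho1 <= radius:
        raise ValueError("wrap_path endpoint inside the wrapping cylinder")
    # 2D frame in the orthogonal plane
    e1 = r0 / rho0
    e2 = np.cross(u, e1)
    a0 = np.array([rho0, 0.0])
    a1 = np.array([r1 @ e1, r1 @ e2])

    def seg_clears():
        # min distance from the origin to segment a0-a1 in 2D
        d = a1 - a0
        t = np.clip(-(a0 @ d) / max(d @ d, 1e-300), 0.0, 1.0)
        return np.linalg.norm(a0 + t * d) >= radius

    if seg_clears():
        return float(np.linalg.norm(p1 - p0)), np.empty((0, 3))

    ang0 = 0.0
    ang1 = np.arctan2(a1[1], a1[0])
    alpha0 = np.arccos(np.clip(radius / rho0, -1, 1))
    alpha1 = np.arccos(np.clip(radius / rho1, -1, 1))
    t0 = np.sqrt(max(rho0**2 - radius**2, 0.0))
    t1 = np.sqrt(max(rho1**2 - radius**2, 0.0))
    dpsi = np.arctan2(np.sin(ang1 - ang0), np.cos(ang1 - ang0))
    side = 1.0 if dpsi >= 0 else -1.0
    arc = abs(dpsi) - alpha0 - alpha1
    if arc <= 0:  # tangent cone overlaps; effectively clears
        return float(np.linalg.norm(p1 - p0)), np.empty((0, 3))
    planar = t0 + t1 + radius * arc
    dz = z1 - z0
    total = float(np.hypot(planar, dz))

    # via points along the arc, axial coordinate by planar path fraction
    phi_t0 = ang0 + side * alpha0  # tangent point from p0
    n_via = max(2, int(np.ceil(arc / 0.2)))
    phis = phi_t0 + side * np.linspace(0.0, arc, n_via)
    s = t0 + radius * np.linspace(0.0, arc, n_via)  # planar arclength at via pts
    zs = z0 + dz * s / planar
    via = c + np.outer(zs, u) + radius * (
        np.outer(np.cos(phis), e1) + np.outer(np.sin(phis), e2)
    )
    return total, via


@dataclass
class DistributedAttachment:
    """Ligament anchor spread over ~20 FEM surface nodes (convex weights)."""

    body: str  # FemBody name
    node_ids: np.ndarray
    weights: np.ndarray
    reference_point: np.ndarray

    def point(self, positions: np.ndarray) -> np.ndarray:
        return self.weights @ positions[self.node_ids]

    def distribute(self, force: np.ndarray) -> np.ndarray:
        """(n,3) nodal forces summing exactly to ``force``."""
        return np.outer(self.weights, force)


def build_distributed_attachment(
    fem_body, point, n_target: int = 20, radius: float = 5e-3
) -> DistributedAttachment:
    """Attach at the ~n_target surface nodes nearest to ``point``.

    Weights are inverse-distance, normalized to sum to one, so an applied
    force is redistributed exactly.
    """
    point = np.asarray(point, float)
    surf = fem_body.surface_nodes
    d = np.linalg.norm(fem_body.positions[surf] - point, axis=1)
    in_radius = np.nonzero(d <= radius)[0]
    if len(in_radius) < 4:
        raise ValueError(
            f"only {len(in_radius)} surface nodes within {radius * 1e3:.1f} mm of "
            "the attachment point (need >= 4); increase the radius"
        )
    order = in_radius[np.argsort(d[in_radius])][:n_target]
    ids = surf[order]
    dd = np.maximum(d[order], 1e-9)
    w = 1.0 / dd
    w = w / w.sum()
    return DistributedAttachment(fem_body.name, ids, w, point.copy())


@dataclass
class LigamentCable:
    """Slack cable of the TMJ capsule.

    Ends are either a rigid-body local point or a DistributedAttachment
    on a disk.  ``slack_length`` is set at assembly time from the initial
    path length plus the per-ligament slack offset.
    """

    name: str
    end_a: tuple[str, np.ndarray] | DistributedAttachment
    end_b: tuple[str, np.ndarray] | DistributedAttachment
    slack_length: float = 0.0
    modulus: float = 250e6  # Pa
    area: float = 1e-6  # m^2 nominal cross-section
    wrap: WrapCylinder | None = None

    @property
    def k_eff(self) -> float:
        return self.modulus * self.area / self.slack_length


def ligament_tension(cable: LigamentCable, path_length: float) -> float:
    """0 below the slack length, then k_eff (L - L_slack); continuous at onset."""
    if path_length <= 0:
        raise ValueError("path length must be positive")
    stretch = path_length - cable.slack_length
    return float(cable.k_eff * stretch) if stretch > 0 else 0.0
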