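"""Parametric synthetic jaw anatomy.

Builds an anatomically plausible stand-in for subject-specific geometry:
an ellipsoidal condyle under a conforming articular fossa whose shape is
a degree-3 sagittal / degree-2 mediolateral polynomial eminence, a
biconcave disk meshed between the two cartilage layers, a convex-hull
mandible with mesh-derived inertia (assumed mass 200 g), flat occlusal
tooth plates, 12 muscle lines per side and 4 capsule ligaments per
joint with the standard slack offsets (posterior +7.5 mm, anterior
+4 mm, medial +1.9 mm, lateral +2.5 mm).

Frame: x anterior, y left, z up; condyle centres at (0, +/-w/2, 0).
All AnatomyParams lengths are millimetres; the built system is SI.

The geometry is deterministic from the parameters; randomness (seed)
only drives optional left/right asymmetry scaling and attachment
jitter.  Muscle strengths are literature-informed placeholders, not
subject-specific values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .actuators import HillMuscle, LigamentCable, WrapCylinder, build_distributed_attachment
from .ef_contact import EFLayer
from .fem import FemBody, MooneyRivlinMaterial
from .mesh_io import TetMesh, TriMesh
from .rigid_body import RigidBody
from .system import ContactPair, JawSystem, Landmark
from .tasks import ActivationSchedule

MM = 1e-3

__all__ = ["AnatomyParams", "generate_anatomy", "generate_disk_mesh", "default_tasks",
           "AnatomyBundle"]


@dataclass(frozen=True)
class AnatomyParams:
    """All lengths in millimetres."""

    condyle_semiaxes: tuple = (8.0, 10.0, 7.0)  # (anterior, mediolateral, vertical)
    intercondylar_width: float = 100.0
    # articular eminence shape added to the disk top / fossa surface:
    # e(x, y) = s1 x + s2 x^2 + s3 x^3 + m2 y^2   (degree 3 sagittal, 2 mediolateral).
    # Default: a glenoid cup (zero slope, positive curvature at the seated
    # condyle) whose cubic term forms the articular eminence descent
    # anterior of x ~ 3 mm and a rising posterior wall.
    fossa_sagittal: tuple = (0.0, 0.08, -0.012)
    fossa_mediolateral: float = 0.05
    disk_footprint: tuple = (6.2, 7.8)  # semi-axes
    disk_thickness_center: float = 1.2
    disk_thickness_periphery: float = 2.5
    disk_mass_kg: float = 0.006
    cartilage_thickness: float = 0.4
    cartilage_modulus_pa: float = 2.7e6
    cartilage_poisson: float = 0.49
    # occlusal contact layer: lumped periodontal-ligament/enamel compliance
    tooth_layer_thickness: float = 1.0
    tooth_layer_modulus_pa: float = 0.5e6
    bite_gap: float = 0.02  # initial incisal clearance, mm
    seating_gap: float = 0.02  # initial disk clearance, mm
    edge_length: float = 1.2  # disk lattice edge, mm (<= central thickness)
    mandible_mass_kg: float = 0.2
    material: MooneyRivlinMaterial = field(default_factory=MooneyRivlinMaterial)
    asymmetry: float = 0.0  # relative left/right scale perturbation
    attachment_jitter: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self):
        if min(self.condyle_semiaxes) <= 0 or min(self.disk_footprint) <= 0:
            raise ValueError("all lengths must be positive")
        if self.edge_length > self.disk_thickness_center:
            raise ValueError("lattice edge length exceeds the central disk thickness")


# ------------------------------------------------------------------ meshing


def _square_to_ellipse(u, v, rx, ry):
    """Smooth area-preserving-ish map of [-1,1]^2 onto an ellipse."""
    x = u * np.sqrt(np.maximum(1.0 - 0.5 * v**2, 0.0)) * rx
    y = v * np.sqrt(np.maximum(1.0 - 0.5 * u**2, 0.0)) * ry
    return x, y


def _grid_surface(rx, ry, n, z_fn, center=(0.0, 0.0), orient_up=True):
    """Triangulated graph surface z = z_fn(x, y) over an ellipse patch."""
    u = np.linspace(-1, 1, n + 1)
    U, V = np.meshgrid(u, u, indexing="ij")
    X, Y = _square_to_ellipse(U, V, rx, ry)
    X = X + center[0]
    Y = Y + center[1]
    Z = z_fn(X, Y)
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    idx = np.arange((n + 1) * (n + 1)).reshape(n + 1, n + 1)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], axis=-1).reshape(-1, 3)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    faces = np.concatenate([f1, f2])
    if not orient_up:
        faces = faces[:, ::-1]
    return TriMesh(verts, faces)


def _ellipse_plan(rx, ry, edge_length):
    """Well-shaped planar point set + triangulation of an ellipse.

    Interior points on a hexagonal lattice of spacing ~edge_length, a
    boundary ring resampled uniformly by arc length, Delaunay
    triangulated (the domain is convex, so the triangulation covers it
    exactly).  Returns (points (n,2), triangles (m,3)).
    """
    from scipy.spatial import Delaunay

    e = edge_length
    # boundary ring, uniform arc length
    th = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    bx, by = rx * np.cos(th), ry * np.sin(th)
    seg = np.hypot(np.diff(bx, append=bx[0]), np.diff(by, append=by[0]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    per = arc[-1]
    n_b = max(8, int(round(per / e)))
    s = np.linspace(0, per, n_b, endpoint=False)
    thb = np.interp(s, arc[:-1], th)
    ring = np.stack([rx * np.cos(thb), ry * np.sin(thb)], axis=1)
    # hexagonal interior lattice
    rows = []
    ny = int(np.ceil(2 * ry / (e * np.sqrt(3) / 2))) + 2
    for j in range(-ny, ny + 1):
        y = j * e * np.sqrt(3) / 2
        off = 0.5 * e if j % 2 else 0.0
        nx = int(np.ceil(2 * rx / e)) + 2
        for i in range(-nx, nx + 1):
            rows.append((i * e + off, y))
    pts = np.array(rows)
    rho = (pts[:, 0] / rx) ** 2 + (pts[:, 1] / ry) ** 2
    # keep lattice points clear of the boundary ring to avoid slivers
    keep = rho <= 1.0
    d_ring = np.min(
        np.linalg.norm(pts[keep][:, None, :] - ring[None, :, :], axis=2), axis=1
    )
    interior = pts[keep][d_ring > 0.55 * e]
    all_pts = np.concatenate([ring, interior])
    tri = Delaunay(all_pts)
    return all_pts, tri.simplices


def generate_disk_mesh(
    footprint,
    thickness_center: float,
    thickness_periphery: float,
    edge_length: float,
    z_bottom_fn=None,
    z_extra_fn=None,
    center=(0.0, 0.0),
) -> TetMesh:
    """Tetrahedralize a biconcave disk with a prismatic lattice.

    ``footprint`` are ellipse semi-axes (mm); thickness varies
    quadratically from the centre to the periphery (clamped to a 1 mm
    minimum for element quality).  The in-plane triangulation (hex
    lattice + Delaunay) is extruded through the thickness and each prism
    split into three tets with an index-ordering rule that keeps shared
    faces conforming.  ``z_bottom_fn`` / ``z_extra_fn`` optionally curve
    the slab over an articular surface; by default the disk is flat with
    its bottom at z = 0.  Lengths and output coordinates in mm (callers
    convert to SI).
    """
    rx, ry = footprint
    if edge_length > thickness_center:
        raise ValueError("edge length exceeds the central disk thickness")
    plan_pts, plan_tris = _ellipse_plan(rx, ry, edge_length)
    t_mean = 0.5 * (thickness_center + thickness_periphery)
    nw = max(2, int(round(t_mean / edge_length)))

    X = plan_pts[:, 0]
    Y = plan_pts[:, 1]
    Xc, Yc = X + center[0], Y + center[1]
    rho2 = (X / rx) ** 2 + (Y / ry) ** 2
    t = thickness_center + (thickness_periphery - thickness_center) * rho2
    if z_extra_fn is not None:
        t = np.maximum(t + z_extra_fn(Xc, Yc), 1.0)
    zb = z_bottom_fn(Xc, Yc) if z_bottom_fn is not None else np.zeros_like(Xc)

    n_p = len(plan_pts)
    nodes = np.empty((n_p, nw + 1, 3))
    for k in range(nw + 1):
        w = k / nw
        nodes[:, k, 0] = Xc
        nodes[:, k, 1] = Yc
        nodes[:, k, 2] = zb + w * t

    def nid(p, k):
        return p * (nw + 1) + k

    tets = []
    for tri0 in plan_tris:
        a, b, c = sorted(int(v) for v in tri0)  # global-order rule -> conforming
        for k in range(nw):
            tets.append([nid(a, k), nid(b, k), nid(c, k), nid(a, k + 1)])
            tets.append([nid(b, k), nid(c, k), nid(a, k + 1), nid(b, k + 1)])
            tets.append([nid(c, k), nid(a, k + 1), nid(b, k + 1), nid(c, k + 1)])
    return TetMesh(nodes.reshape(-1, 3), np.array(tets, int))


# ------------------------------------------------------------------ anatomy


def _muscle_table(width):
    """(name, group, origin body, origin xyz, insertion xyz on mandible), right side.

    Coordinates in mm for the right side (y < 0); mirrored for the left.
    f_max are literature-informed placeholders.
    """
    y = -width / 2  # condyle centre line, right side
    return [
        # name, group, origin body, origin, insertion (on mandible), f_max
        ("temporalis_ant", "closer", "skull", (20, y + 5, 45), (22, y + 5, 0), 40.0),
        ("temporalis_mid", "closer", "skull", (0, y + 2, 50), (20, y + 5, -2), 40.0),
        ("temporalis_post", "closer", "skull", (-15, y + 5, 40), (18, y + 5, -4), 25.0),
        ("masseter_sup", "closer", "skull", (34, y, 10), (14, y + 2, -35), 55.0),
        ("masseter_deep", "closer", "skull", (18, y, 8), (12, y + 2, -25), 25.0),
        ("medial_pterygoid", "closer", "skull", (16, y + 12, 5), (10, y + 5, -33), 45.0),
        ("lateral_pterygoid_sup", "lateral_pterygoid", "skull", (18, y + 15, 2),
         (8, y, -2), 25.0),
        ("lateral_pterygoid_inf", "lateral_pterygoid", "skull", (18, y + 15, -5),
         (6, y, -5), 35.0),
        ("digastric_ant", "submental", "hyoid", (55, y + 42, -60), (85, y + 45, -45), 25.0),
        ("geniohyoid", "submental", "hyoid", (55, y + 45, -65), (86, y + 47, -43), 22.0),
        ("mylohyoid_ant", "submental", "hyoid", (55, y + 40, -63), (75, y + 35, -40), 18.0),
        ("mylohyoid_post", "submental", "hyoid", (55, y + 40, -63), (60, y + 30, -35), 18.0),
    ]


@dataclass
class AnatomyBundle:
    system: JawSystem
    params: AnatomyParams
    tasks: dict[str, ActivationSchedule]
    disk_meshes: dict[str, TetMesh]
    surfaces: dict[str, TriMesh]  # named surface meshes (mm-independent, SI)


def default_tasks() -> dict[str, ActivationSchedule]:
    """The four forward-simulation tasks.

    rest: steady 0.08 % closer activity (postural tone); open: maximal
    lateral pterygoid + submental ramp over 0.25 s, held; protrude:
    maximal lateral pterygoid with low closer/submental co-activation;
    clench: maximal closer ramp, held.
    """
    rest = ActivationSchedule("rest").set("closer", [(0.0, 0.0008)])
    open_ = (
        ActivationSchedule("open")
        .set("lateral_pterygoid", [(0.0, 0.0), (0.25, 1.0)])
        .set("submental", [(0.0, 0.0), (0.25, 1.0)])
        .set("closer", [(0.0, 0.0008), (0.25, 0.0)])
    )
    protrude = (
        ActivationSchedule("protrude")
        .set("lateral_pterygoid", [(0.0, 0.0), (0.25, 1.0)])
        .set("closer", [(0.0, 0.0008), (0.25, 0.1)])
        .set("submental", [(0.0, 0.0), (0.25, 0.05)])
    )
    clench = ActivationSchedule("clench").set("closer", [(0.0, 0.02), (0.25, 1.0)])
    return {"rest": rest, "open": open_, "protrude": protrude, "clench": clench}


def generate_anatomy(params: AnatomyParams | None = None) -> AnatomyBundle:
    """Build the full synthetic jaw model as a ready-to-run JawSystem."""
    p = params or AnatomyParams()
    rng = np.random.default_rng(p.seed)
    ax, ay, az = p.condyle_semiaxes
    h = p.cartilage_thickness
    w = p.intercondylar_width
    rx, ry = p.disk_footprint
    s1, s2, s3 = p.fossa_sagittal
    m2 = p.fossa_mediolateral
    gap0 = p.seating_gap
    side_scale = {"right": 1.0 - p.asymmetry * 0.5, "left": 1.0 + p.asymmetry * 0.5}

    def eminence(x, yloc):
        return s1 * x + s2 * x**2 + s3 * x**3 + m2 * yloc**2

    def condyle_cap_z(x, yloc):  # outer cartilage surface over a condyle (local y)
        xi = (x / (ax + h)) ** 2 + (yloc / (ay + h)) ** 2
        return (az + h) * np.sqrt(np.maximum(1.0 - xi, 0.0))

    def condyle_cap_series_z(x, yloc):  # smooth extension used by the fossa
        xi = (x / (ax + h)) ** 2 + (yloc / (ay + h)) ** 2
        return (az + h) * (1.0 - 0.5 * xi - 0.125 * xi**2)

    # ---- per-side articular geometry (mm) -----------------------------
    surfaces: dict[str, TriMesh] = {}
    disk_meshes: dict[str, TetMesh] = {}
    condyle_pts = []
    for side, sgn in (("right", -1.0), ("left", 1.0)):
        sc = side_scale[side]
        yc = sgn * w / 2
        caxes = (ax * sc, ay * sc, az * sc)

        def cap(x, y, _yc=yc, _sc=sc):
            return condyle_cap_z((x) * 1.0 / _sc, (y - _yc) / _sc) * _sc

        def cap_series(x, y, _yc=yc, _sc=sc):
            return condyle_cap_series_z(x / _sc, (y - _yc) / _sc) * _sc

        def emin(x, y, _yc=yc):
            return eminence(x, y - _yc)

        def disk_bottom(x, y, _cap=cap_series):
            return _cap(x, y) + gap0

        def thickness_extra(x, y, _emin=emin):
            return _emin(x, y)

        # condyle cartilage patch (on the mandible), normals up/outward
        prx = min(1.15 * rx * sc, 0.94 * (ax + h) * sc)
        pry = min(1.15 * ry * sc, 0.94 * (ay + h) * sc)
        cart = _grid_surface(prx, pry, 14, cap, center=(0.0, yc), orient_up=True)
        surfaces[f"condyle_cartilage_{side}"] = cart

        # disk between the layers
        disk = generate_disk_mesh(
            (rx * sc, ry * sc), p.disk_thickness_center, p.disk_thickness_periphery,
            p.edge_length, z_bottom_fn=disk_bottom, z_extra_fn=thickness_extra,
            center=(0.0, yc),
        )
        disk_meshes[f"disk_{side}"] = disk

        # fossa cartilage (on the skull): exact offset of the disk top,
        # extended anteriorly with the smooth series cap; normals down
        def fossa_z(x, y, _cap=cap_series, _emin=emin):
            rho2 = (x / (rx * sc)) ** 2 + ((y - yc) / (ry * sc)) ** 2
            t = p.disk_thickness_center + (
                p.disk_thickness_periphery - p.disk_thickness_center) * rho2
            t = np.maximum(t + _emin(x, y), 1.0)
            return _cap(x, y) + gap0 + t + gap0

        fossa = _grid_surface(min(1.45 * rx * sc, 12.0), 1.12 * ry * sc, 28, fossa_z,
                              center=(1.5, yc), orient_up=False)
        surfaces[f"fossa_cartilage_{side}"] = fossa

        # condyle sample points for the mandible hull
        sph = _trimesh.creation.icosphere(subdivisions=2)
        pts = np.asarray(sph.vertices) * np.array(caxes) + np.array([0.0, yc, 0.0])
        condyle_pts.append(pts)

    # ---- tooth plates --------------------------------------------------
    plate_x = np.linspace(55.0, 90.0, 8)
    plate_y = np.linspace(-25.0, 25.0, 11)
    PX, PY = np.meshgrid(plate_x, plate_y, indexing="ij")

    def plate(z, orient_up):
        Z = np.full_like(PX, z)
        verts = np.stack([PX.ravel(), PY.ravel(), Z.ravel()], axis=1)
        idx = np.arange(PX.size).reshape(PX.shape)
        f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], axis=-1).reshape(-1, 3)
        f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
        faces = np.concatenate([f1, f2])
        if not orient_up:
            faces = faces[:, ::-1]
        return TriMesh(verts, faces)

    upper_plate = plate(-40.0 + p.bite_gap, orient_up=False)  # outward toward the mandible
    lower_plate = plate(-40.0, orient_up=True)
    surfaces["upper_teeth"] = upper_plate
    surfaces["lower_teeth"] = lower_plate

    # ---- mandible rigid body ------------------------------------------
    hull_pts = np.concatenate(
        condyle_pts
        + [
            np.array(
                [
                    [22, -45, 2], [22, 45, 2],  # coronoid processes
                    [10, -48, -38], [10, 48, -38],  # gonial angles
                    [88, -6, -30], [88, 6, -30], [88, 0, -48],  # chin
                    [55, -25, -40], [55, 25, -40], [90, -25, -40], [90, 25, -40],
                ],
                float,
            )
        ]
    )
    hull = _trimesh.convex.convex_hull(hull_pts * MM)
    mand_mesh = TriMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
    mandible = RigidBody.from_mesh("mandible", mand_mesh, p.mandible_mass_kg, dynamic=True)
    com_mm = mandible.position / MM  # initial pose: world COM

    def mand_local(pts_mm):
        return (np.asarray(pts_mm, float) - com_mm) * MM

    skull = RigidBody(name="skull", dynamic=False)
    hyoid = RigidBody(name="hyoid", dynamic=False)

    system = JawSystem()
    system.add_body(mandible)
    system.add_body(skull)
    system.add_body(hyoid)

    # ---- EF layers and contact pairs ----------------------------------
    for side in ("right", "left"):
        cart = surfaces[f"condyle_cartilage_{side}"]
        system.add_layer(EFLayer(
            f"condyle_{side}", "mandible",
            TriMesh(mand_local(cart.vertices), cart.faces),
            thickness=h * MM, elastic_modulus=p.cartilage_modulus_pa,
            poisson=p.cartilage_poisson,
        ))
        fossa = surfaces[f"fossa_cartilage_{side}"]
        system.add_layer(EFLayer(
            f"fossa_{side}", "skull", TriMesh(fossa.vertices * MM, fossa.faces),
            thickness=h * MM, elastic_modulus=p.cartilage_modulus_pa,
            poisson=p.cartilage_poisson,
        ))
    system.add_layer(EFLayer(
        "upper_teeth", "skull", TriMesh(upper_plate.vertices * MM, upper_plate.faces),
        thickness=p.tooth_layer_thickness * MM, elastic_modulus=p.tooth_layer_modulus_pa,
        poisson=p.cartilage_poisson, damping_s=0.1,
    ))

    # ---- FEM disks -----------------------------------------------------
    for side in ("right", "left"):
        tm = disk_meshes[f"disk_{side}"]
        fb = FemBody(f"disk_{side}", TetMesh(tm.nodes * MM, tm.tets), p.material,
                     total_mass=p.disk_mass_kg, allow_inversion=True)
        system.add_fem_body(fb)
        system.contact_pairs.append(ContactPair(f"disk_{side}", f"condyle_{side}", "fem"))
        system.contact_pairs.append(ContactPair(f"disk_{side}", f"fossa_{side}", "fem"))
    system.contact_pairs.append(ContactPair(
        "mandible", "upper_teeth", "rigid",
        rigid_mesh=TriMesh(mand_local(lower_plate.vertices), lower_plate.faces),
    ))

    # ---- muscles -------------------------------------------------------
    for side, sgn in (("right", 1.0), ("left", -1.0)):
        for name, group, obody, org, ins, f_max in _muscle_table(w):
            org = np.array(org, float) * np.array([1.0, sgn, 1.0])
            ins = np.array(ins, float) * np.array([1.0, sgn, 1.0])
            if p.attachment_jitter > 0:
                org = org + rng.normal(scale=p.attachment_jitter, size=3)
                ins = ins + rng.normal(scale=p.attachment_jitter, size=3)
            system.muscles.append(HillMuscle(
                name=f"{name}_{side}", group=group,
                origin_body=obody, origin_point=np.asarray(org) * MM,
                insertion_body="mandible", insertion_point=mand_local(ins),
                f_max=f_max,
            ))

    # ---- ligaments -----------------------------------------------------
    system.finalize()  # dof layout needed before distributed attachments
    slack_offsets = {"posterior": 7.5, "anterior": 4.0, "medial": 1.9, "lateral": 2.5}
    for side, sgn in (("right", -1.0), ("left", 1.0)):
        yc = sgn * w / 2
        sc = side_scale[side]
        fb = system.fem_bodies[f"disk_{side}"]
        zmid = float(fb.positions[:, 2].mean()) / MM
        rim = {
            "anterior": (rx * sc - 0.5, yc, zmid),
            "posterior": (-rx * sc + 0.5, yc, zmid),
            "medial": (0.0, yc - sgn * (ry * sc - 0.5), zmid),
            "lateral": (0.0, yc + sgn * (ry * sc - 0.5), zmid),
        }
        bone = {
            "anterior": ("mandible", mand_local((ax * sc + 2.0, yc, -3.0))),
            "posterior": ("skull", np.array((-12.0, yc, 6.0)) * MM),
            "medial": ("mandible", mand_local((0.0, yc - sgn * (ay * sc + 1.0), 0.0))),
            "lateral": ("mandible", mand_local((0.0, yc + sgn * (ay * sc + 1.0), 0.0))),
        }
        for kind in ("anterior", "posterior", "medial", "lateral"):
            anchor = build_distributed_attachment(
                fb, np.asarray(rim[kind], float) * MM, n_target=20, radius=4e-3)
            wrap = None
            if kind == "anterior":
                wrap = WrapCylinder(
                    body="mandible", point=mand_local((0.0, yc, -2.0)),
                    axis=np.array([0.0, 1.0, 0.0]), radius=4.5 * MM,
                )
            lig = LigamentCable(
                name=f"{kind}_ligament_{side}", end_a=anchor, end_b=bone[kind], wrap=wrap,
            )
            # slack length = initial path length + the per-ligament offset
            pA = system._end_point(lig.end_a)
            pB = system._end_point(lig.end_b)
            if wrap is not None:
                from .actuators import wrap_path

                wb = system.bodies[wrap.body]
                L0, _ = wrap_path(pA, pB, wb.world_point(wrap.point),
                                  wb.rotation @ wrap.axis, wrap.radius)
            else:
                L0 = float(np.linalg.norm(pB - pA))
            lig.slack_length = L0 + slack_offsets[kind] * MM
            system.ligaments.append(lig)

    # ---- landmarks -----------------------------------------------------
    system.landmarks["incisor_upper"] = Landmark(
        "skull", np.array([90.0, 0.0, -40.0 + p.bite_gap]) * MM)
    system.landmarks["incisor_lower"] = Landmark("mandible", mand_local((90.0, 0.0, -40.0)))
    system.finalize()

    _check_seating(system, p)
    return AnatomyBundle(system=system, params=p, tasks=default_tasks(),
                         disk_meshes=disk_meshes, surfaces=surfaces)


def _check_seating(system: JawSystem, p: AnatomyParams):
    """Generation-time guarantee: no initial penetration beyond 0.5 h."""
    _, _, _, contact_sets = system.evaluate({}, with_stiffness=False)
    for (pen, layer), cs in contact_sets.items():
        if len(cs.depths):
            worst = float(cs.depths.max() / system.ef_layers[layer].thickness)
            if worst > 0.5:
                raise ValueError(
                    f"generated anatomy has initial interpenetration {worst:.2f} h "
                    f"between {pen!r} and {layer!r}; adjust seating_gap or geometry"
                )
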