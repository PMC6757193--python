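"""Model configuration: YAML schema, validation, bundle write/load, manifests.

A model lives in a run directory:

    model.yaml      - bodies, disks, materials, layers, muscles, ligaments,
                      landmarks, integrator defaults
    tasks.yaml      - activation schedules (piecewise linear, per muscle
                      or muscle group)
    meshes/         - OBJ surfaces (millimetres) and TetGen .node/.ele pairs

Lengths in the YAML are millimetres (converted to SI at load); moduli
and forces are SI (Pa, N).  ``validate_config`` collects *all*
violations with JSON-pointer-style paths instead of failing fast.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .actuators import HillMuscle, LigamentCable, WrapCylinder, build_distributed_attachment
from .ef_contact import EFLayer
from .fem import FemBody, MooneyRivlinMaterial
from .integrator import SimConfig
from .mesh_io import MM, TriMesh, read_surface, read_tetgen, write_obj, write_tetgen
from .rigid_body import RigidBody, inertia_from_mesh
from .system import ContactPair, JawSystem, Landmark
from .tasks import ActivationSchedule

__all__ = ["ConfigError", "validate_config", "load_model", "load_tasks", "write_bundle",
           "write_manifest"]


class ConfigError(ValueError):
    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(self.violations))


def _vec(x, n=3):
    return np.asarray(x, float).reshape(n)


# ------------------------------------------------------------------ validation

_TOP_KEYS = {"unit_scale", "gravity", "seed", "bodies", "fem_bodies", "ef_layers",
             "contact_pairs", "muscles", "ligaments", "landmarks", "integrator"}


def validate_config(path) -> list[str]:
    """Validate a model.yaml; returns the (possibly empty) violation list.

    Each violation is a JSON-pointer-style path plus a message.  Unknown
    keys are rejected; physical ranges (Poisson ratio, thicknesses,
    masses) are checked.
    """
    path = Path(path)
    out: list[str] = []
    try:
        cfg = yaml.safe_load(path.read_text())
    except Exception as e:
        return [f"/: unreadable YAML: {e}"]
    if not isinstance(cfg, dict):
        return ["/: config must be a mapping"]

    for key in cfg:
        if key not in _TOP_KEYS:
            out.append(f"/{key}: unknown key")

    def need(key, typ, where="/"):
        if key not in cfg:
            out.append(f"{where}{key}: missing")
            return None
        return cfg[key]

    def check_vec(v, ptr):
        try:
            _vec(v)
        except Exception:
            out.append(f"{ptr}: expected a 3-vector")

    bodies = need("bodies", list)
    body_names = set()
    if isinstance(bodies, list):
        for i, b in enumerate(bodies):
            ptr = f"/bodies/{i}"
            if not isinstance(b, dict) or "name" not in b:
                out.append(f"{ptr}: body needs a name")
                continue
            body_names.add(b["name"])
            if b.get("dynamic", False):
                if "mesh" not in b:
                    out.append(f"{ptr}/mesh: dynamic body needs a mesh")
                if not (isinstance(b.get("mass"), (int, float)) and b.get("mass", 0) > 0):
                    out.append(f"{ptr}/mass: dynamic body needs positive mass")
            if "mesh" in b and not (path.parent / b["mesh"]).exists():
                out.append(f"{ptr}/mesh: file not found: {b['mesh']}")

    fem_names = set()
    for i, fb in enumerate(cfg.get("fem_bodies", []) or []):
        ptr = f"/fem_bodies/{i}"
        if "name" not in fb:
            out.append(f"{ptr}: needs a name")
            continue
        fem_names.add(fb["name"])
        for key in ("node", "ele"):
            if key not in fb:
                out.append(f"{ptr}/{key}: missing TetGen file reference")
            elif not (path.parent / fb[key]).exists():
                out.append(f"{ptr}/{key}: file not found: {fb[key]}")
        mat = fb.get("material", {})
        if mat.get("C1", 1.0) <= 0:
            out.append(f"{ptr}/material/C1: must be positive")
        if mat.get("C2", 0.0) < 0:
            out.append(f"{ptr}/material/C2: must be non-negative")
        kappa = mat.get("kappa")
        if kappa is not None and kappa < 100 * mat.get("C1", 9e5):
            out.append(f"{ptr}/material/kappa: must be >= 100 C1")
        if fb.get("mass_kg", 1.0) <= 0:
            out.append(f"{ptr}/mass_kg: must be positive")

    layer_names = set()
    for i, l in enumerate(cfg.get("ef_layers", []) or []):
        ptr = f"/ef_layers/{i}"
        if "name" not in l:
            out.append(f"{ptr}: needs a name")
            continue
        layer_names.add(l["name"])
        if l.get("body") not in body_names:
            out.append(f"{ptr}/body: unknown body {l.get('body')!r}")
        if "mesh" in l and not (path.parent / l["mesh"]).exists():
            out.append(f"{ptr}/mesh: file not found: {l['mesh']}")
        nu = l.get("poisson", 0.49)
        if not (0 <= nu < 0.5):
            out.append(
                f"{ptr}/poisson: {nu} is invalid (0 <= nu < 0.5; the foundation "
                "stiffness is singular at nu = 0.5)"
            )
        if l.get("thickness_mm", 0.4) <= 0:
            out.append(f"{ptr}/thickness_mm: must be positive")
        if l.get("elastic_modulus_pa", 2.7e6) <= 0:
            out.append(f"{ptr}/elastic_modulus_pa: must be positive")

    for i, p in enumerate(cfg.get("contact_pairs", []) or []):
        ptr = f"/contact_pairs/{i}"
        if p.get("layer") not in layer_names:
            out.append(f"{ptr}/layer: unknown layer {p.get('layer')!r}")
        kind = p.get("kind", "fem")
        if kind == "fem" and p.get("penetrator") not in fem_names:
            out.append(f"{ptr}/penetrator: unknown FEM body {p.get('penetrator')!r}")
        if kind == "rigid":
            if p.get("penetrator") not in body_names:
                out.append(f"{ptr}/penetrator: unknown body {p.get('penetrator')!r}")
            if "mesh" not in p:
                out.append(f"{ptr}/mesh: rigid pair needs a collision mesh")

    for i, m in enumerate(cfg.get("muscles", []) or []):
        ptr = f"/muscles/{i}"
        for end in ("origin", "insertion"):
            e = m.get(end, {})
            if e.get("body") not in body_names:
                out.append(f"{ptr}/{end}/body: unknown body {e.get('body')!r}")
            if "point_mm" in e:
                check_vec(e["point_mm"], f"{ptr}/{end}/point_mm")
            else:
                out.append(f"{ptr}/{end}/point_mm: missing")
        if m.get("f_max", 0) <= 0:
            out.append(f"{ptr}/f_max: must be positive")

    for i, l in enumerate(cfg.get("ligaments", []) or []):
        ptr = f"/ligaments/{i}"
        for end in ("end_a", "end_b"):
            e = l.get(end, {})
            if "fem" in e:
                if e["fem"] not in fem_names:
                    out.append(f"{ptr}/{end}/fem: unknown FEM body {e['fem']!r}")
            elif e.get("body") not in body_names:
                out.append(f"{ptr}/{end}/body: unknown body {e.get('body')!r}")
        if l.get("slack_length_mm", 1.0) <= 0:
            out.append(f"{ptr}/slack_length_mm: must be positive")
        if l.get("modulus_pa", 250e6) <= 0:
            out.append(f"{ptr}/modulus_pa: must be positive")

    integ = cfg.get("integrator", {}) or {}
    if integ.get("dt", 1e-3) <= 0:
        out.append("/integrator/dt: must be positive")
    return out


# ------------------------------------------------------------------ loading


def load_model(path) -> JawSystem:
    """Build a JawSystem from a validated model.yaml."""
    path = Path(path)
    violations = validate_config(path)
    if violations:
        raise ConfigError(violations)
    cfg = yaml.safe_load(path.read_text())
    root = path.parent
    scale = float(cfg.get("unit_scale", MM))

    system = JawSystem(gravity=cfg.get("gravity", (0.0, 0.0, -9.81)))
    integ = cfg.get("integrator", {}) or {}
    system.linear_drag = float(integ.get("linear_drag", system.linear_drag))
    system.angular_drag = float(integ.get("angular_drag", system.angular_drag))
    system.fem_damping_beta = float(integ.get("fem_damping_beta", system.fem_damping_beta))

    for b in cfg["bodies"]:
        mesh = None
        if "mesh" in b:
            mesh = read_surface(root / b["mesh"], unit_scale=scale)
        if b.get("dynamic", False):
            com, inertia = inertia_from_mesh(mesh, float(b["mass"]))
            body = RigidBody(name=b["name"], mesh=TriMesh(mesh.vertices - com, mesh.faces),
                             mass=float(b["mass"]), inertia=inertia, dynamic=True)
            body.position = com + _vec(b.get("position_mm", (0, 0, 0))) * scale
        else:
            body = RigidBody(name=b["name"], mesh=mesh, dynamic=False)
            body.position = _vec(b.get("position_mm", (0, 0, 0))) * scale
        system.add_body(body)

    for fb in cfg.get("fem_bodies", []) or []:
        mat = fb.get("material", {})
        material = MooneyRivlinMaterial(
            C1=float(mat.get("C1", 9e5)), C2=float(mat.get("C2", 9e2)),
            kappa=mat.get("kappa"),
        )
        mesh = read_tetgen(root / fb["node"], root / fb["ele"], unit_scale=scale)
        system.add_fem_body(FemBody(fb["name"], mesh, material,
                                    total_mass=float(fb.get("mass_kg", 0.006))))

    for l in cfg.get("ef_layers", []) or []:
        surf = read_surface(root / l["mesh"], unit_scale=scale)
        system.add_layer(EFLayer(
            l["name"], l["body"], surf,
            thickness=float(l.get("thickness_mm", 0.4)) * 1e-3,
            elastic_modulus=float(l.get("elastic_modulus_pa", 2.7e6)),
            poisson=float(l.get("poisson", 0.49)),
        ))

    for p in cfg.get("contact_pairs", []) or []:
        kind = p.get("kind", "fem")
        rigid_mesh = None
        if kind == "rigid":
            rigid_mesh = read_surface(root / p["mesh"], unit_scale=scale)
        system.contact_pairs.append(ContactPair(p["penetrator"], p["layer"], kind,
                                                rigid_mesh=rigid_mesh))

    for m in cfg.get("muscles", []) or []:
        system.muscles.append(HillMuscle(
            name=m["name"], group=m.get("group", ""),
            origin_body=m["origin"]["body"],
            origin_point=_vec(m["origin"]["point_mm"]) * scale,
            insertion_body=m["insertion"]["body"],
            insertion_point=_vec(m["insertion"]["point_mm"]) * scale,
            f_max=float(m["f_max"]),
            l_opt=(float(m["l_opt_mm"]) * scale) if "l_opt_mm" in m else None,
            damping=m.get("damping"),
        ))

    system.finalize()  # dof layout before distributed attachments

    for l in cfg.get("ligaments", []) or []:
        ends = []
        for key in ("end_a", "end_b"):
            e = l[key]
            if "fem" in e:
                ends.append(build_distributed_attachment(
                    system.fem_bodies[e["fem"]], _vec(e["point_mm"]) * scale,
                    n_target=int(e.get("n_nodes", 20)),
                    radius=float(e.get("radius_mm", 4.0)) * 1e-3,
                ))
            else:
                ends.append((e["body"], _vec(e["point_mm"]) * scale))
        wrap = None
        if "wrap" in l:
            w = l["wrap"]
            wrap = WrapCylinder(w["body"], _vec(w["point_mm"]) * scale,
                                _vec(w["axis"]), float(w["radius_mm"]) * 1e-3)
        system.ligaments.append(LigamentCable(
            name=l["name"], end_a=ends[0], end_b=ends[1],
            slack_length=float(l["slack_length_mm"]) * 1e-3,
            modulus=float(l.get("modulus_pa", 250e6)),
            area=float(l.get("area_mm2", 1.0)) * 1e-6,
            wrap=wrap,
        ))

    for name, lm in (cfg.get("landmarks", {}) or {}).items():
        system.landmarks[name] = Landmark(lm["body"], _vec(lm["point_mm"]) * scale)
    system.finalize()
    return system


def load_tasks(path) -> dict[str, ActivationSchedule]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {name: ActivationSchedule.from_dict(name, d) for name, d in raw.items()}


def sim_config_from_yaml(path, **overrides) -> SimConfig:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    integ = dict(cfg.get("integrator", {}) or {})
    integ.pop("linear_drag", None); integ.pop("angular_drag", None)
    integ.pop("fem_damping_beta", None)
    integ.update(overrides)
    return SimConfig(**integ)


# ------------------------------------------------------------------ writing


def write_bundle(bundle, outdir) -> Path:
    """Write a synthetic AnatomyBundle as a run directory (model + tasks + meshes)."""
    outdir = Path(outdir)
    (outdir / "meshes").mkdir(parents=True, exist_ok=True)
    s = bundle.system
    scale = MM

    cfg: dict = {
        "unit_scale": scale,
        "gravity": [float(g) for g in s.gravity],
        "seed": int(bundle.params.seed),
        "bodies": [],
        "fem_bodies": [],
        "ef_layers": [],
        "contact_pairs": [],
        "muscles": [],
        "ligaments": [],
        "landmarks": {},
        "integrator": {"dt": 1e-3,
                       "linear_drag": s.linear_drag, "angular_drag": s.angular_drag,
                       "fem_damping_beta": s.fem_damping_beta},
    }
    for name, b in s.bodies.items():
        entry: dict = {"name": name, "dynamic": bool(b.dynamic)}
        if b.mesh is not None and len(b.mesh.vertices):
            rel = f"meshes/{name}.obj"
            write_obj(outdir / rel, b.mesh, unit_scale=scale)
            entry["mesh"] = rel
        if b.dynamic:
            entry["mass"] = float(b.mass)
            # the stored mesh is COM-local; position restores the world pose
            entry["position_mm"] = [0.0, 0.0, 0.0]
        else:
            entry["position_mm"] = [float(x / scale) for x in b.position]
        cfg["bodies"].append(entry)
    # dynamic body: loader recomputes COM from the local mesh (~0) and places
    # the body at com + position_mm; write position so the pose round-trips
    for entry in cfg["bodies"]:
        if entry.get("dynamic"):
            b = s.bodies[entry["name"]]
            com, _ = inertia_from_mesh(b.mesh, b.mass)
            entry["position_mm"] = [float(x / scale) for x in (b.position - com)]

    for name, fb in s.fem_bodies.items():
        node_rel, ele_rel = f"meshes/{name}.node", f"meshes/{name}.ele"
        write_tetgen(outdir / node_rel, outdir / ele_rel, fb.mesh, unit_scale=scale)
        cfg["fem_bodies"].append({
            "name": name, "node": node_rel, "ele": ele_rel,
            "mass_kg": float(fb.node_mass.sum()),
            "material": {"C1": fb.material.C1, "C2": fb.material.C2,
                         "kappa": fb.material.kappa},
        })
    for name, layer in s.ef_layers.items():
        rel = f"meshes/layer_{name}.obj"
        write_obj(outdir / rel, layer.surface, unit_scale=scale)
        cfg["ef_layers"].append({
            "name": name, "body": layer.body, "mesh": rel,
            "thickness_mm": layer.thickness * 1e3,
            "elastic_modulus_pa": layer.elastic_modulus,
            "poisson": layer.poisson,
        })
    for pair in s.contact_pairs:
        entry = {"penetrator": pair.penetrator, "layer": pair.layer, "kind": pair.kind}
        if pair.kind == "rigid":
            rel = f"meshes/collision_{pair.penetrator}_{pair.layer}.obj"
            write_obj(outdir / rel, pair.rigid_mesh, unit_scale=scale)
            entry["mesh"] = rel
        cfg["contact_pairs"].append(entry)
    for m in s.muscles:
        cfg["muscles"].append({
            "name": m.name, "group": m.group, "f_max": float(m.f_max),
            "l_opt_mm": float(m.l_opt / scale),
            "origin": {"body": m.origin_body,
                       "point_mm": [float(x / scale) for x in m.origin_point]},
            "insertion": {"body": m.insertion_body,
                          "point_mm": [float(x / scale) for x in m.insertion_point]},
        })
    from .actuators import DistributedAttachment

    for l in s.ligaments:
        def end_dict(end):
            if isinstance(end, DistributedAttachment):
                return {"fem": end.body, "n_nodes": len(end.node_ids), "radius_mm": 4.0,
                        "point_mm": [float(x / scale) for x in end.reference_point]}
            return {"body": end[0], "point_mm": [float(x / scale) for x in end[1]]}

        entry = {
            "name": l.name, "end_a": end_dict(l.end_a), "end_b": end_dict(l.end_b),
            "slack_length_mm": float(l.slack_length / scale),
            "modulus_pa": float(l.modulus), "area_mm2": float(l.area / 1e-6),
        }
        if l.wrap is not None:
            entry["wrap"] = {"body": l.wrap.body,
                             "point_mm": [float(x / scale) for x in l.wrap.point],
                             "axis": [float(a) for a in l.wrap.axis],
                             "radius_mm": float(l.wrap.radius / 1e-3)}
        cfg["ligaments"].append(entry)
    for name, lm in s.landmarks.items():
        cfg["landmarks"][name] = {"body": lm.body,
                                  "point_mm": [float(x / scale) for x in lm.point]}

    (outdir / "model.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    (outdir / "tasks.yaml").write_text(yaml.safe_dump(
        {name: t.to_dict() for name, t in bundle.tasks.items()}, sort_keys=False))
    write_manifest(outdir, {"params": asdict_params(bundle.params)})
    return outdir


def asdict_params(params):
    d = asdict(params)
    d["material"] = {"C1": params.material.C1, "C2": params.material.C2,
                     "kappa": params.material.kappa}
    return d


def write_manifest(outdir, extra=None):
    """Run provenance: config snapshot hashes, versions, parameters."""
    from . import __version__

    outdir = Path(outdir)
    hashes = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            hashes[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"tool": "tmjsim", "version": __version__, "inputs_sha256": hashes}
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
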