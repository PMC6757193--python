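"""Mesh containers, file I/O and validation metrics.

Internal units are SI (metres); files default to millimetres via
``unit_scale``.  Surface meshes come in as OBJ (hand parser, so format
errors can name the offending line) or STL (delegated to trimesh);
volume meshes as TetGen ``.node``/``.ele`` pairs in either index base.
Simulation fields go out as legacy ASCII VTK, one file per frame.

Validation metrics mirror the model-checking pipeline: per-tet
circumsphere-radius / shortest-edge ratio and maximal dihedral angle,
and symmetric vertex-sampled Hausdorff distance statistics between two
surfaces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .surface import closest_surface_points

MM = 1e-3  #: default file unit scale (millimetres -> metres)

__all__ = [
    "TriMesh",
    "TetMesh",
    "QualityReport",
    "DistanceReport",
    "MeshFormatError",
    "MeshDataError",
    "read_surface",
    "write_obj",
    "read_tetgen",
    "write_tetgen",
    "write_vtk_frame",
    "tet_quality",
    "hausdorff_stats",
]


class MeshFormatError(ValueError):
    """Unparseable mesh file (message names the line/record)."""


class MeshDataError(ValueError):
    """Parsed but invalid mesh data (bad indices, degenerate entities)."""


@dataclass
class TriMesh:
    """Triangle surface mesh. ``vertices`` (n,3) metres, ``faces`` (m,3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshDataError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshDataError("faces must be (m, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshDataError("non-finite vertex coordinate")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshDataError(
                f"face index out of range (max {self.faces.max()} for "
                f"{len(self.vertices)} vertices)"
            )

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def drop_degenerate_faces(self, rel_tol: float = 1e-12) -> "TriMesh":
        """Remove zero-area faces (load-time cleaning)."""
        a = self.face_areas()
        scale = max(float(a.max(initial=0.0)), 1e-300)
        keep = a > rel_tol * scale
        return TriMesh(self.vertices, self.faces[keep])

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "TriMesh":
        return TriMesh(self.vertices @ R.T + t, self.faces)

    def compact(self) -> "TriMesh":
        """Drop vertices not referenced by any face, remapping indices.

        Surfaces extracted from tet meshes index into the full node array;
        compact before vertex-sampled comparisons (hausdorff_stats) so
        interior nodes do not enter the statistics.
        """
        used = np.unique(self.faces)
        remap = np.full(len(self.vertices), -1, dtype=int)
        remap[used] = np.arange(len(used))
        return TriMesh(self.vertices[used], remap[self.faces])


@dataclass
class TetMesh:
    """Tetrahedral mesh; tets consistently oriented to positive signed volume."""

    nodes: np.ndarray
    tets: np.ndarray

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=int)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshDataError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshDataError("tets must be (m, 4)")
        if len(self.tets) and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise MeshDataError("tet node index out of range")
        vol = self.signed_volumes()
        neg = vol < 0
        if np.any(neg):  # reorient by swapping one node pair
            self.tets[neg] = self.tets[neg][:, [0, 2, 1, 3]]
            vol = self.signed_volumes()
        zero = np.abs(vol) <= 1e-30
        if np.any(zero):
            ids = np.nonzero(zero)[0]
            raise MeshDataError(f"zero-volume tetrahedra: {ids.tolist()[:20]}")

    def signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    @property
    def volume(self) -> float:
        return float(self.signed_volumes().sum())

    def surface(self) -> tuple[TriMesh, np.ndarray]:
        """Extract the boundary surface, outward-oriented.

        Returns the surface TriMesh (indexed into the *full* node array)
        and the array of node indices that lie on the surface.
        """
        # local faces ordered so that their normal points out of the tet
        local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        faces = self.tets[:, local].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        boundary = counts[inv] == 1
        bfaces = faces[boundary]
        surf_nodes = np.unique(bfaces)
        return TriMesh(self.nodes, bfaces), surf_nodes


@dataclass
class QualityReport:
    """Tet-mesh quality: circumsphere-radius/shortest-edge ratio and max dihedral."""

    mean_circum_ratio: float
    mean_max_dihedral: float  # degrees
    circum_ratio: np.ndarray = field(repr=False, default=None)
    max_dihedral: np.ndarray = field(repr=False, default=None)

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {"circum_ratio": self.circum_ratio, "max_dihedral_deg": self.max_dihedral}
        ).to_csv(path, index=False)


@dataclass
class DistanceReport:
    """Symmetric vertex-sampled surface distance statistics, millimetres."""

    minimum: float
    maximum: float
    mean: float
    rms: float

    def as_dict(self):
        return {
            "minimum_mm": self.minimum,
            "maximum_mm": self.maximum,
            "mean_mm": self.mean,
            "rms_mm": self.rms,
        }


# ---------------------------------------------------------------- readers


def _parse_obj(text: str, name: str) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "v":
            if len(tok) < 4:
                raise MeshFormatError(f"{name}:{ln}: vertex record needs 3 coordinates")
            try:
                verts.append([float(t) for t in tok[1:4]])
            except ValueError as e:
                raise MeshFormatError(f"{name}:{ln}: bad vertex coordinate: {e}") from e
        elif tok[0] == "f":
            if len(tok) < 4:
                raise MeshFormatError(f"{name}:{ln}: face record needs >=3 vertices")
            try:
                idx = [int(t.split("/")[0]) for t in tok[1:]]
            except ValueError as e:
                raise MeshFormatError(f"{name}:{ln}: bad face index: {e}") from e
            idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
            for a, b in zip(idx[1:-1], idx[2:]):  # fan-triangulate
                faces.append([idx[0], a, b])
    return np.array(verts, float).reshape(-1, 3), np.array(faces, int).reshape(-1, 3)


def read_surface(path, fmt: str | None = None, unit_scale: float = MM) -> TriMesh:
    """Read an OBJ or STL surface; coordinates are scaled to metres.

    ``fmt`` defaults to the file suffix.  Degenerate (zero-area) faces are
    dropped at load time; out-of-range indices and non-finite coordinates
    raise :class:`MeshDataError`.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "stl"):
        raise MeshFormatError(f"unsupported surface format {fmt!r}")
    if fmt == "obj":
        verts, faces = _parse_obj(path.read_text(), path.name)
        if len(faces) and len(verts) and (faces.min() < 0 or faces.max() >= len(verts)):
            raise MeshDataError(
                f"{path.name}: face references vertex {faces.max() + 1} of {len(verts)}"
            )
    else:
        try:
            tm = _trimesh.load(str(path), file_type="stl", process=False)
        except Exception as e:  # binary/ascii STL parse issues
            raise MeshFormatError(f"{path.name}: STL parse failure: {e}") from e
        verts, faces = np.asarray(tm.vertices, float), np.asarray(tm.faces, int)
    mesh = TriMesh(verts * unit_scale, faces)
    return mesh.drop_degenerate_faces()


def write_obj(path, mesh: TriMesh, unit_scale: float = MM) -> None:
    """Write OBJ, converting from metres back to file units (default mm)."""
    with open(path, "w") as f:
        for v in mesh.vertices / unit_scale:
            f.write(f"v {v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for face in mesh.faces + 1:
            f.write(f"f {face[0]} {face[1]} {face[2]}\n")


def _read_table(path, name):
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            try:
                rows.append(([float(t) for t in line.split()], ln))
            except ValueError as e:
                raise MeshFormatError(f"{name}:{ln}: {e}") from e
    if not rows:
        raise MeshFormatError(f"{name}: empty file")
    return rows


def read_tetgen(node_path, ele_path, unit_scale: float = MM) -> TetMesh:
    """Read a TetGen ``.node``/``.ele`` pair.

    Both 0- and 1-based index dialects are supported; the base is taken
    from the first node label.  Tets are reoriented to positive volume.
    """
    nrows = _read_table(node_path, Path(node_path).name)
    header, _ = nrows[0]
    n_nodes = int(header[0])
    body = nrows[1:]
    if len(body) != n_nodes:
        raise MeshDataError(
            f"{Path(node_path).name}: header says {n_nodes} nodes, found {len(body)}"
        )
    labels = np.array([int(r[0][0]) for r in body])
    base = int(labels.min())
    if base not in (0, 1):
        raise MeshDataError(f"{Path(node_path).name}: first node index must be 0 or 1")
    order = np.argsort(labels)
    nodes = np.array([body[i][0][1:4] for i in order], float) * unit_scale

    erows = _read_table(ele_path, Path(ele_path).name)
    n_ele = int(erows[0][0][0])
    ebody = erows[1:]
    if len(ebody) != n_ele:
        raise MeshDataError(
            f"{Path(ele_path).name}: header says {n_ele} tets, found {len(ebody)}"
        )
    tets = np.array([[int(v) for v in r[0][1:5]] for r in ebody], int) - base
    if tets.min() < 0 or tets.max() >= n_nodes:
        raise MeshDataError(f"{Path(ele_path).name}: tet node index out of range")
    return TetMesh(nodes, tets)


def write_tetgen(node_path, ele_path, mesh: TetMesh, unit_scale: float = MM) -> None:
    with open(node_path, "w") as f:
        f.write(f"{len(mesh.nodes)} 3 0 0\n")
        for i, p in enumerate(mesh.nodes / unit_scale):
            f.write(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
    with open(ele_path, "w") as f:
        f.write(f"{len(mesh.tets)} 4 0\n")
        for i, t in enumerate(mesh.tets):
            f.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")


# ---------------------------------------------------------------- VTK output


def write_vtk_frame(path, mesh, point_fields=None, cell_fields=None, unit_scale: float = MM):
    """Write one legacy-ASCII VTK unstructured-grid frame.

    ``mesh`` may be a TriMesh or TetMesh.  ``point_fields`` / ``cell_fields``
    map names to scalar (n,) or vector (n,3) arrays; lengths must match the
    mesh entity counts.
    """
    point_fields = point_fields or {}
    cell_fields = cell_fields or {}
    if isinstance(mesh, TetMesh):
        pts, cells, cell_type = mesh.nodes, mesh.tets, 10
    else:
        pts, cells, cell_type = mesh.vertices, mesh.faces, 5
    for name, arr in point_fields.items():
        if len(np.asarray(arr)) != len(pts):
            raise ValueError(f"point field {name!r} has length {len(arr)} != {len(pts)}")
    for name, arr in cell_fields.items():
        if len(np.asarray(arr)) != len(cells):
            raise ValueError(f"cell field {name!r} has length {len(arr)} != {len(cells)}")

    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\ntmjsim frame\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {len(pts)} float\n")
    for p in pts / unit_scale:
        buf.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    k = cells.shape[1]
    buf.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
    for c in cells:
        buf.write(f"{k} " + " ".join(str(i) for i in c) + "\n")
    buf.write(f"CELL_TYPES {len(cells)}\n")
    buf.write("\n".join([str(cell_type)] * len(cells)) + ("\n" if len(cells) else ""))

    def _write_fields(fields, n, kind):
        buf.write(f"{kind} {n}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                buf.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                buf.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
            else:
                buf.write(f"VECTORS {name} float\n")
                for v in arr:
                    buf.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")

    if point_fields:
        _write_fields(point_fields, len(pts), "POINT_DATA")
    if cell_fields:
        _write_fields(cell_fields, len(cells), "CELL_DATA")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------- metrics


def tet_quality(mesh: TetMesh) -> QualityReport:
    """Per-tet circumsphere-radius / shortest-edge ratio and max dihedral angle.

    The ratio is bounded below by sqrt(3/8) ~ 0.6124, attained by the
    regular tetrahedron; the dihedral angle is measured between face
    planes interior to the tet, maximized over the six edges.
    """
    p = mesh.nodes[mesh.tets]  # (m,4,3)
    # circumcenter: solve 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2
    a = 2.0 * (p[:, 1:] - p[:, :1])  # (m,3,3)
    rhs = np.einsum("mij,mij->mi", p[:, 1:], p[:, 1:]) - np.einsum(
        "mj,mj->m", p[:, 0], p[:, 0]
    )[:, None]
    c = np.linalg.solve(a, rhs[..., None])[..., 0]
    R = np.linalg.norm(c - p[:, 0], axis=1)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(p[:, i] - p[:, j], axis=1) for i, j in pairs], axis=1)
    ratio = R / edges.min(axis=1)

    # outward face normals; faces opposite node k
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    normals = np.empty((len(p), 4, 3))
    for k in range(4):
        f = p[:, local[k]]
        n = np.cross(f[:, 1] - f[:, 0], f[:, 2] - f[:, 0])
        # orient outward: away from the opposite node
        s = np.sign(np.einsum("mi,mi->m", n, f[:, 0] - p[:, k]))
        normals[:, k] = n * (s / np.linalg.norm(n, axis=1))[:, None]
    # dihedral at the edge shared by faces (i, j): pi - angle(n_i, n_j)
    face_pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    dih = np.empty((len(p), 6))
    for e, (i, j) in enumerate(face_pairs):
        cosang = np.clip(np.einsum("mi,mi->m", normals[:, i], normals[:, j]), -1, 1)
        dih[:, e] = np.degrees(np.pi - np.arccos(cosang))
    max_dih = dih.max(axis=1)
    return QualityReport(
        mean_circum_ratio=float(ratio.mean()),
        mean_max_dihedral=float(max_dih.mean()),
        circum_ratio=ratio,
        max_dihedral=max_dih,
    )


def hausdorff_stats(a: TriMesh, b: TriMesh) -> DistanceReport:
    """Symmetric vertex-to-surface distance statistics in millimetres.

    Distances from every vertex of ``a`` to surface ``b`` and vice versa
    are pooled; min/max/mean/RMS are computed over the pooled sample.
    The maximum equals the classical symmetric Hausdorff distance under
    vertex sampling.
    """
    if len(a.vertices) == 0 or len(b.vertices) == 0 or len(a.faces) == 0 or len(b.faces) == 0:
        raise ValueError("hausdorff_stats requires two non-empty meshes")
    _, _, d_ab = closest_surface_points(a.vertices, b.vertices, b.faces)
    _, _, d_ba = closest_surface_points(b.vertices, a.vertices, a.faces)
    d = np.concatenate([d_ab, d_ba]) / MM
    return DistanceReport(
        minimum=float(d.min()),
        maximum=float(d.max()),
        mean=float(d.mean()),
        rms=float(np.sqrt(np.mean(d**2))),
    )
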