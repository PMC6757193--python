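import numpy as np
import pytest

from tmjsim.mesh_io import (
    MeshDataError,
    MeshFormatError,
    TetMesh,
    TriMesh,
    hausdorff_stats,
    read_surface,
    read_tetgen,
    tet_quality,
    write_obj,
    write_tetgen,
    write_vtk_frame,
)


class TestReadSurface:
    def test_obj_parse(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3\nf 1 3 4\n")
        m = read_surface(p)
        assert len(m.vertices) == 4 and len(m.faces) == 2
        assert np.allclose(m.vertices.max(), 1e-3)  # mm -> m

    def test_obj_unit_scale(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = read_surface(p, unit_scale=1.0)
        assert np.allclose(m.vertices.max(), 1.0)

    def test_obj_out_of_range_index(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nv 0 0 1\nf 1 2 9\n")
        with pytest.raises((MeshDataError, MeshFormatError)):
            read_surface(p)

    def test_obj_bad_line_named(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv one 0 0\n")
        with pytest.raises(MeshFormatError, match="bad.obj:2"):
            read_surface(p)

    def test_stl_cube_scaling(self, tmp_path):
        import trimesh

        box = trimesh.creation.box(extents=(1, 1, 1))
        box.apply_translation([0.5, 0.5, 0.5])
        p = tmp_path / "cube.stl"
        box.export(str(p))
        m = read_surface(p, unit_scale=1e-3)
        assert m.vertices.min() >= -1e-12 and m.vertices.max() <= 1e-3 + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(MeshDataError):
            TriMesh(np.array([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]]), [[0, 1, 2]])

    def test_obj_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = TriMesh(rng.random((10, 3)) * 1e-2, [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        p = tmp_path / "rt.obj"
        write_obj(p, m)
        m2 = read_surface(p)
        assert np.allclose(m2.vertices, m.vertices, rtol=1e-9, atol=1e-15)
        assert np.array_equal(m2.faces, m.faces)


class TestTetgen:
    def _write(self, tmp_path, base):
        nodes = "4 3 0 0\n" + "\n".join(
            f"{i + base} {x} {y} {z}"
            for i, (x, y, z) in enumerate([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        )
        eles = f"1 4 0\n{base} {base} {base + 1} {base + 2} {base + 3}\n"
        (tmp_path / "m.node").write_text(nodes + "\n")
        (tmp_path / "m.ele").write_text(eles)
        return tmp_path / "m.node", tmp_path / "m.ele"

    @pytest.mark.parametrize("base", [0, 1])
    def test_both_index_dialects(self, tmp_path, base):
        n, e = self._write(tmp_path, base)
        m = read_tetgen(n, e)
        assert len(m.nodes) == 4 and len(m.tets) == 1
        assert m.volume > 0

    def test_negative_orientation_fixed(self, tmp_path):
        (tmp_path / "m.node").write_text(
            "4 3 0 0\n0 0 0 0\n1 1 0 0\n2 0 1 0\n3 0 0 1\n")
        (tmp_path / "m.ele").write_text("1 4 0\n0 0 2 1 3\n")  # negative volume order
        m = read_tetgen(tmp_path / "m.node", tmp_path / "m.ele")
        assert m.signed_volumes()[0] > 0

    def test_index_out_of_range(self, tmp_path):
        (tmp_path / "m.node").write_text("3 3 0 0\n0 0 0 0\n1 1 0 0\n2 0 1 0\n")
        (tmp_path / "m.ele").write_text("1 4 0\n0 0 1 2 7\n")
        with pytest.raises(MeshDataError):
            read_tetgen(tmp_path / "m.node", tmp_path / "m.ele")

    def test_roundtrip(self, tmp_path, regular_tet):
        write_tetgen(tmp_path / "r.node", tmp_path / "r.ele", regular_tet, unit_scale=1.0)
        m = read_tetgen(tmp_path / "r.node", tmp_path / "r.ele", unit_scale=1.0)
        assert np.allclose(m.nodes, regular_tet.nodes, rtol=1e-9)
        assert np.array_equal(m.tets, regular_tet.tets)


class TestVtk:
    def test_point_scalar_written(self, tmp_path, regular_tet):
        p = tmp_path / "f_000000.vtk"
        write_vtk_frame(p, regular_tet, point_fields={"von_mises": np.arange(4.0)})
        text = p.read_text()
        assert "SCALARS von_mises" in text and "POINTS 4" in text
        assert "CELL_TYPES" in text

    def test_geometry_only(self, tmp_path, unit_square_plate):
        p = tmp_path / "g.vtk"
        write_vtk_frame(p, unit_square_plate)
        assert "POINT_DATA" not in p.read_text()

    def test_wrong_length_rejected(self, tmp_path, regular_tet):
        with pytest.raises(ValueError):
            write_vtk_frame(tmp_path / "x.vtk", regular_tet,
                            point_fields={"f": np.zeros(7)})


class TestTetQuality:
    def test_regular_tet_is_minimizer(self, regular_tet):
        q = tet_quality(regular_tet)
        assert q.mean_circum_ratio == pytest.approx(np.sqrt(3.0 / 8.0), abs=1e-9)
        assert q.mean_max_dihedral == pytest.approx(70.528779, abs=1e-4)

    def test_two_identical_tets_same_mean(self, regular_tet):
        nodes = np.concatenate([regular_tet.nodes, regular_tet.nodes + 10.0])
        mesh = TetMesh(nodes, [[0, 1, 2, 3], [4, 5, 6, 7]])
        q2 = tet_quality(mesh)
        q1 = tet_quality(regular_tet)
        assert q2.mean_circum_ratio == pytest.approx(q1.mean_circum_ratio, rel=1e-12)
        assert q2.mean_max_dihedral == pytest.approx(q1.mean_max_dihedral, rel=1e-12)

    def test_corner_tet_closed_form(self, corner_tet):
        q = tet_quality(corner_tet)
        assert q.mean_circum_ratio == pytest.approx(np.sqrt(3) / 2, abs=1e-9)

    def test_lower_bound_on_random_meshes(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            nodes = rng.random((4, 3))
            try:
                mesh = TetMesh(nodes, [[0, 1, 2, 3]])
            except MeshDataError:
                continue
            q = tet_quality(mesh)
            assert np.all(q.circum_ratio >= np.sqrt(3.0 / 8.0) - 1e-12)
            assert np.all((q.max_dihedral > 0) & (q.max_dihedral < 180))


class TestHausdorff:
    def test_identity_zero(self, unit_square_plate):
        rep = hausdorff_stats(unit_square_plate, unit_square_plate)
        assert rep.minimum == rep.maximum == rep.mean == rep.rms == 0.0

    def test_parallel_plates(self):
        n = 8
        g = np.linspace(0, 1e-3, n)
        X, Y = np.meshgrid(g, g, indexing="ij")

        def plate(z):
            verts = np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=1)
            idx = np.arange(n * n).reshape(n, n)
            f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], -1).reshape(-1, 3)
            f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 3)
            return TriMesh(verts, np.concatenate([f1, f2]))

        rep = hausdorff_stats(plate(0.0), plate(0.5e-3))
        assert rep.mean == pytest.approx(0.5, abs=1e-9)
        assert rep.maximum == pytest.approx(0.5, abs=1e-9)

    def test_normal_offset_triangle(self):
        tri = TriMesh(np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0]]), [[0, 1, 2]])
        tri2 = TriMesh(tri.vertices + [0, 0, 2e-3], tri.faces)
        rep = hausdorff_stats(tri, tri2)
        assert rep.maximum == pytest.approx(2.0, abs=1e-9)
        assert rep.mean == pytest.approx(2.0, abs=1e-9)
        assert rep.rms == pytest.approx(2.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = TriMesh(rng.random((9, 3)) * 1e-2, [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        b = TriMesh(rng.random((9, 3)) * 1e-2, [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        r1, r2 = hausdorff_stats(a, b), hausdorff_stats(b, a)
        assert r1.as_dict() == r2.as_dict()

    def test_max_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = TriMesh(rng.random((6, 3)) * 1e-2, [[0, 1, 2], [3, 4, 5]])
        b = TriMesh(rng.random((6, 3)) * 1e-2, [[0, 1, 2], [3, 4, 5]])
        rep = hausdorff_stats(a, b)

        def one_sided(src, dst):
            best = []
            for p in src.vertices:
                d = np.inf
                tri = dst.vertices[dst.faces]
                for f in tri:
                    for u in np.linspace(0, 1, 60):
                        for v in np.linspace(0, 1 - u, max(2, int(60 * (1 - u)) + 1)):
                            q = f[0] + u * (f[1] - f[0]) + v * (f[2] - f[0])
                            d = min(d, np.linalg.norm(p - q))
                best.append(d)
            return max(best)

        brute = max(one_sided(a, b), one_sided(b, a)) / 1e-3
        assert rep.maximum == pytest.approx(brute, rel=1e-2)

    def test_empty_mesh_rejected(self, unit_square_plate):
        empty = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            hausdorff_stats(unit_square_plate, empty)
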