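"""Hex mesh I/O, morphing, and the six element-quality metrics."""

import numpy as np
import pytest

from headmorph.dispfield import DisplacementField
from headmorph.hexmesh import (
    HexMesh,
    MeshFormatError,
    aspect_ratio,
    face_angles,
    morph_mesh,
    quality_report,
    read_mesh,
    scaled_jacobian,
    skew,
    warpage,
    write_mesh,
)

UNIT_CUBE = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)


def single_hex(nodes, part="brain"):
    return HexMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=np.arange(8).reshape(1, 8),
        parts=np.array([part], dtype=object),
    )


def two_cube_mesh():
    """Two unit cubes sharing the x = 1 face."""
    shifted = UNIT_CUBE + [1.0, 0, 0]
    nodes = np.vstack([UNIT_CUBE, shifted])
    # merge duplicate nodes on the shared face
    uniq, inv = np.unique(np.round(nodes, 9), axis=0, return_inverse=True)
    elements = inv[np.arange(16)].reshape(2, 8)
    return HexMesh(
        nodes=uniq, elements=elements, parts=np.array(["a", "b"], dtype=object)
    )


def brute_force_corner_jacobian(corners):
    """Independent min corner determinant with normalized edges."""
    neighbours = {
        0: (1, 3, 4), 1: (2, 0, 5), 2: (3, 1, 6), 3: (0, 2, 7),
        4: (7, 5, 0), 5: (4, 6, 1), 6: (5, 7, 2), 7: (6, 4, 3),
    }
    vals = []
    for c, (a, b, d) in neighbours.items():
        e = [corners[n] - corners[c] for n in (a, b, d)]
        e = [v / np.linalg.norm(v) for v in e]
        vals.append(np.linalg.det(np.stack(e)))
    return min(vals)


class TestMeshIO:
    @pytest.mark.parametrize("dialect", ["vtk", "vtu", "abaqus"])
    def test_single_cube_round_trip(self, tmp_path, dialect):
        mesh = single_hex(UNIT_CUBE)
        suffix = {"vtk": ".vtk", "vtu": ".vtu", "abaqus": ".inp"}[dialect]
        p = tmp_path / f"cube{suffix}"
        write_mesh(mesh, p, dialect)
        back = read_mesh(p, dialect)
        np.testing.assert_allclose(back.nodes, mesh.nodes, atol=1e-9)
        np.testing.assert_array_equal(back.elements, mesh.elements)
        assert back.parts.tolist() == mesh.parts.tolist()

    @pytest.mark.parametrize("dialect", ["vtk", "vtu", "abaqus"])
    def test_two_part_mesh_keeps_labels(self, tmp_path, dialect):
        mesh = two_cube_mesh()
        suffix = {"vtk": ".vtk", "vtu": ".vtu", "abaqus": ".inp"}[dialect]
        p = tmp_path / f"two{suffix}"
        write_mesh(mesh, p, dialect)
        back = read_mesh(p, dialect)
        assert sorted(back.parts.tolist()) == ["a", "b"]
        # same node sets per part even if element order changed
        for part in ("a", "b"):
            orig = mesh.nodes[mesh.elements[mesh.parts == part][0]]
            new = back.nodes[back.elements[back.parts == part][0]]
            assert set(map(tuple, np.round(orig, 6))) == set(
                map(tuple, np.round(new, 6))
            )

    def test_tetra_cell_rejected(self, tmp_path):
        p = tmp_path / "tet.vtk"
        p.write_text(
            "# vtk DataFile Version 3.0\nt\nASCII\nDATASET UNSTRUCTURED_GRID\n"
            "POINTS 4 double\n0 0 0\n1 0 0\n0 1 0\n0 0 1\n"
            "CELLS 1 5\n4 0 1 2 3\nCELL_TYPES 1\n10\n"
        )
        with pytest.raises(MeshFormatError, match="10"):
            read_mesh(p)

    def test_quad_shells_survive_vtk_round_trip(self, tmp_path):
        mesh = HexMesh(
            nodes=UNIT_CUBE,
            elements=np.arange(8).reshape(1, 8),
            parts=np.array(["brain"], dtype=object),
            quads=np.array([[0, 1, 2, 3]]),
            quad_parts=np.array(["skull"], dtype=object),
        )
        p = tmp_path / "shell.vtk"
        write_mesh(mesh, p)
        back = read_mesh(p)
        assert back.quads is not None and len(back.quads) == 1
        assert back.quad_parts.tolist() == ["skull"]

    def test_duplicate_node_in_element_rejected(self):
        el = np.array([[0, 0, 1, 2, 3, 4, 5, 6]])
        with pytest.raises(MeshFormatError):
            HexMesh(nodes=UNIT_CUBE, elements=el, parts=np.array(["a"], object))


class TestMorphMesh:
    def test_zero_field_identity(self, field_factory):
        f = field_factory(lambda x: np.zeros_like(x), shape=(8, 8, 8))
        mesh = single_hex(UNIT_CUBE)
        out = morph_mesh(mesh, f)
        np.testing.assert_array_equal(out.nodes, mesh.nodes)
        np.testing.assert_array_equal(out.elements, mesh.elements)

    def test_uniform_translation_shifts_all_nodes(self, field_factory):
        t = np.array([2.0, -1.0, 0.5])
        f = field_factory(
            lambda x: np.broadcast_to(t, x.shape).copy(), shape=(16, 16, 16)
        )
        mesh = single_hex(UNIT_CUBE)
        out = morph_mesh(mesh, f)
        np.testing.assert_allclose(out.nodes, mesh.nodes + t, atol=1e-9)
        before = quality_report(mesh)
        after = quality_report(out)
        for k in before.extrema:
            assert after.extrema[k] == pytest.approx(before.extrema[k], abs=1e-9)

    def test_linear_field_gives_affine_nodes(self, field_factory):
        A = np.array([[0.1, 0.05, 0], [0, -0.08, 0.02], [0.01, 0, 0.06]])
        f = field_factory(lambda x: x @ A.T, shape=(16, 16, 16))
        mesh = single_hex(UNIT_CUBE)
        out = morph_mesh(mesh, f)
        np.testing.assert_allclose(
            out.nodes, mesh.nodes @ (np.eye(3) + A).T, atol=1e-9
        )

    def test_parts_and_connectivity_untouched(self, field_factory):
        f = field_factory(lambda x: np.sin(x), shape=(12, 12, 12))
        mesh = two_cube_mesh()
        out = morph_mesh(mesh, f)
        np.testing.assert_array_equal(out.elements, mesh.elements)
        assert out.parts.tolist() == mesh.parts.tolist()


class TestScaledJacobian:
    def test_unit_cube_is_one(self):
        assert scaled_jacobian(single_hex(UNIT_CUBE), 0) == pytest.approx(1.0)

    def test_inverted_corner_goes_negative(self):
        bad = UNIT_CUBE.copy()
        bad[6] = [-0.5, -0.5, -0.5]  # pull a corner through the opposite side
        assert scaled_jacobian(single_hex(bad), 0) < 0

    def test_shear_matches_brute_force_oracle(self):
        sheared = UNIT_CUBE + np.stack(
            [0.5 * UNIT_CUBE[:, 1], np.zeros(8), np.zeros(8)], axis=1
        )
        got = scaled_jacobian(single_hex(sheared), 0)
        assert got == pytest.approx(brute_force_corner_jacobian(sheared), abs=1e-12)

    def test_uniform_scaling_invariant(self):
        rng = np.random.default_rng(7)
        wiggled = UNIT_CUBE + rng.normal(0, 0.08, (8, 3))
        a = scaled_jacobian(single_hex(wiggled), 0)
        b = scaled_jacobian(single_hex(wiggled * 3.7), 0)
        assert a == pytest.approx(b, abs=1e-12)


class TestQualityMetrics:
    def test_perfect_cube_reference_values(self):
        mesh = two_cube_mesh()
        rep = quality_report(mesh)
        assert all(v == 100.0 for v in rep.percentages.values())
        assert rep.extrema["min_angle"] == pytest.approx(90.0)
        assert rep.extrema["max_angle"] == pytest.approx(90.0)
        assert rep.extrema["aspect_ratio"] == pytest.approx(1.0)
        assert rep.extrema["warpage"] == pytest.approx(0.0, abs=1e-6)
        assert rep.extrema["skew"] == pytest.approx(0.0, abs=1e-6)

    def test_one_inverted_element_among_many(self):
        cubes = []
        for i in range(100):
            cubes.append(UNIT_CUBE + [2.0 * i, 0, 0])
        nodes = np.vstack(cubes)
        elements = np.arange(800).reshape(100, 8)
        mesh = HexMesh(
            nodes=nodes, elements=elements,
            parts=np.array(["a"] * 100, dtype=object),
        )
        # invert one element by swapping its top and bottom faces
        mesh.nodes[8 * 7: 8 * 7 + 8] = np.vstack(
            [cubes[7][4:], cubes[7][:4]]
        )
        rep = quality_report(mesh)
        assert rep.percentages["scaled_jacobian"] == pytest.approx(99.0)
        assert rep.extrema["scaled_jacobian"] < 0
        assert rep.worst_elements["scaled_jacobian"] == 7

    def test_rigid_motion_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(8)
        wiggled = UNIT_CUBE + rng.normal(0, 0.1, (8, 3))
        mesh = single_hex(wiggled)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = single_hex(wiggled @ R.T + [10.0, -4.0, 2.0])
        a, b = quality_report(mesh), quality_report(moved)
        for k in a.extrema:
            assert a.extrema[k] == pytest.approx(b.extrema[k], abs=1e-9)

    def test_aspect_ratio_of_stretched_cube(self):
        stretched = UNIT_CUBE * [4.0, 1.0, 1.0]
        assert aspect_ratio(single_hex(stretched))[0] == pytest.approx(4.0)

    def test_warped_face_detected(self):
        warped = UNIT_CUBE.copy()
        warped[6, 2] += 0.4  # lift one top corner out of plane
        assert warpage(single_hex(warped))[0] > 5.0
        assert skew(single_hex(UNIT_CUBE))[0] == pytest.approx(0.0, abs=1e-9)

    def test_face_angles_of_sheared_cube(self):
        sheared = UNIT_CUBE + np.stack(
            [UNIT_CUBE[:, 1], np.zeros(8), np.zeros(8)], axis=1
        )
        amin, amax = face_angles(single_hex(sheared))
        assert amin[0] == pytest.approx(45.0)
        assert amax[0] == pytest.approx(135.0)

    def test_empty_mesh_rejected(self):
        mesh = HexMesh(
            nodes=UNIT_CUBE,
            elements=np.empty((0, 8), dtype=np.int64),
            parts=np.array([], dtype=object),
        )
        with pytest.raises(ValueError):
            quality_report(mesh)

    def test_report_matches_per_element_recomputation(self):
        rng = np.random.default_rng(9)
        cubes = [
            UNIT_CUBE + rng.normal(0, 0.1, (8, 3)) + [2.5 * i, 0, 0]
            for i in range(20)
        ]
        mesh = HexMesh(
            nodes=np.vstack(cubes),
            elements=np.arange(160).reshape(20, 8),
            parts=np.array(["a"] * 20, dtype=object),
        )
        rep = quality_report(mesh)
        sj_each = [
            brute_force_corner_jacobian(mesh.nodes[el]) for el in mesh.elements
        ]
        np.testing.assert_allclose(rep.values["scaled_jacobian"], sj_each, atol=1e-12)
        assert rep.extrema["scaled_jacobian"] == pytest.approx(min(sj_each))
        assert rep.percentages["scaled_jacobian"] == pytest.approx(
            100.0 * np.mean(np.asarray(sj_each) >= 0.5)
        )
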