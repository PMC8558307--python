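"""Displacement-field algebra: sampling, summation, inversion, warping."""

import numpy as np
import pytest

from headmorph.dispfield import (
    DisplacementField,
    InversionError,
    field_jacobian_map,
    invert_field,
    load_external_field,
    read_field,
    sample_field,
    sum_fields,
    warp_by_inverse_chain,
    warp_image,
    write_field,
    zero_field,
)
from headmorph.evalmetrics import dice
from headmorph.imagevol import LabelMask, VolumeImage


class TestSampleField:
    def test_zero_field_everywhere_zero(self, field_factory):
        f = field_factory(lambda x: np.zeros_like(x))
        pts = np.array([[0.0, 0, 0], [1.7, -2.3, 0.4], [100.0, 100, 100]])
        np.testing.assert_allclose(sample_field(f, pts), 0.0)

    def test_constant_field_interior(self, field_factory):
        t = np.array([1.0, -2.0, 0.5])
        f = field_factory(lambda x: np.broadcast_to(t, x.shape).copy())
        np.testing.assert_allclose(sample_field(f, [0.3, 0.7, -1.2]), t)

    def test_linear_field_reproduced_exactly(self, field_factory):
        A = np.array([[0.1, 0.02, 0.0], [0.0, -0.05, 0.01], [0.03, 0.0, 0.08]])
        f = field_factory(lambda x: x @ A.T)
        p = np.array([0.37, -1.21, 2.05])  # non-lattice interior point
        np.testing.assert_allclose(sample_field(f, p), A @ p, atol=1e-12)

    def test_outside_support_returns_zero(self, field_factory):
        f = field_factory(lambda x: np.ones_like(x))
        np.testing.assert_allclose(sample_field(f, [1e4, 0, 0]), 0.0)


class TestSumFields:
    def test_zero_is_identity_element(self, field_factory):
        f = field_factory(lambda x: x * 0.1)
        z = DisplacementField(
            vectors=np.zeros_like(f.vectors), affine=f.affine, tag="zero"
        )
        np.testing.assert_array_equal(sum_fields([f, z]).vectors, f.vectors)

    def test_translations_add(self, field_factory):
        t1, t2 = np.array([1.0, 0, 0]), np.array([0, 2.0, -1.0])
        f1 = field_factory(lambda x: np.broadcast_to(t1, x.shape).copy())
        f2 = field_factory(lambda x: np.broadcast_to(t2, x.shape).copy())
        np.testing.assert_allclose(sum_fields([f1, f2]).vectors[3, 3, 3], t1 + t2)

    def test_commutative_and_associative(self, field_factory):
        rng = np.random.default_rng(4)
        fs = [
            field_factory(lambda x, s=s: np.sin(x / 5 + s))
            for s in rng.normal(size=3)
        ]
        a = sum_fields([fs[0], fs[1], fs[2]]).vectors
        b = sum_fields([fs[2], fs[0], fs[1]]).vectors
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_grid_mismatch_names_field(self, field_factory):
        f1 = field_factory(lambda x: x * 0.0, tag="g_demo")
        f2 = field_factory(lambda x: x * 0.0, spacing=2.0, tag="g_f1")
        with pytest.raises(ValueError, match="g_f1"):
            sum_fields([f1, f2])


class TestInvertField:
    def test_zero_field_inverts_to_zero(self, field_factory):
        f = field_factory(lambda x: np.zeros_like(x))
        np.testing.assert_allclose(invert_field(f).vectors, 0.0)

    def test_translation_inverts_to_negative(self, field_factory):
        t = np.array([0.4, -0.2, 0.1])
        f = field_factory(
            lambda x: np.broadcast_to(t, x.shape).copy(), shape=(16, 16, 16)
        )
        h = invert_field(f, tol=1e-6)
        interior = h.vectors[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(
            interior, np.broadcast_to(-t, interior.shape), atol=1e-6
        )

    def test_radial_expansion_residual_below_tol(self, field_factory):
        def radial(x):
            r = np.linalg.norm(x, axis=-1, keepdims=True)
            return 0.15 * x * np.exp(-((r / 4.0) ** 2))

        f = field_factory(radial, shape=(20, 20, 20))
        tol = 0.01
        h = invert_field(f, tol=tol)
        X = f.grid().grid_world_coords()
        res = sample_field(f, X + h.vectors) + h.vectors
        assert np.linalg.norm(res[1:-1, 1:-1, 1:-1], axis=-1).max() <= tol

    def test_nonconvergence_reports_residual(self, field_factory):
        # folding field (J < 0): fixed point cannot reach tolerance
        f = field_factory(lambda x: -1.8 * x, shape=(10, 10, 10))
        with pytest.raises(InversionError, match="residual|invertible"):
            invert_field(f, tol=1e-9, max_iter=3, strict=True)


class TestWarpImage:
    def test_zero_field_is_identity(self, field_factory):
        f = field_factory(lambda x: np.zeros_like(x), shape=(10, 10, 10))
        rng = np.random.default_rng(5)
        img = VolumeImage(data=rng.normal(size=(10, 10, 10)), affine=f.affine)
        np.testing.assert_allclose(warp_image(img, f).data, img.data, atol=1e-12)

    def test_translation_moves_feature_backwards(self, field_factory):
        # pull-back: out(x) = img(x + t) puts the bright voxel at index - t
        f = field_factory(
            lambda x: np.broadcast_to([2.0, 0, 0], x.shape).copy(),
            shape=(12, 12, 12),
            spacing=1.0,
        )
        img = VolumeImage(data=np.zeros((12, 12, 12)), affine=f.affine)
        img.data[6, 6, 6] = 1.0
        out = warp_image(img, f)
        assert out.data[4, 6, 6] == pytest.approx(1.0)
        assert out.data[6, 6, 6] == pytest.approx(0.0)

    def test_warp_roundtrip_dice(self, field_factory):
        def radial(x):
            r = np.linalg.norm(x, axis=-1, keepdims=True)
            return 0.8 * x * np.exp(-((r / 6.0) ** 2))

        f = field_factory(radial, shape=(24, 24, 24))
        idx = np.stack(np.meshgrid(*(np.arange(24),) * 3, indexing="ij"), -1)
        blob = np.linalg.norm(idx - 11.5, axis=-1) <= 6
        mask = LabelMask(data=blob.astype(np.uint8), affine=f.affine)
        back = warp_image(warp_image(mask, f), invert_field(f, tol=1e-3))
        assert dice(back, mask) >= 0.99

    def test_mean_preserved_for_volume_preserving_field(self, field_factory):
        # a shear u = (0.3*y, 0, 0) has det(I + grad u) = 1 everywhere
        f = field_factory(
            lambda x: np.stack(
                [0.3 * x[..., 1], np.zeros(x.shape[:-1]), np.zeros(x.shape[:-1])],
                axis=-1,
            ),
            shape=(24, 24, 24),
        )
        xyz = f.grid().grid_world_coords()
        smooth = np.exp(-np.linalg.norm(xyz, axis=-1) ** 2 / 40.0)
        img = VolumeImage(data=smooth, affine=f.affine)
        out = warp_image(img, f)
        assert abs(out.data.mean() - img.data.mean()) / img.data.mean() < 0.01


class TestInverseChain:
    def test_single_step_reduces_to_inverse_warp(self, field_factory):
        def radial(x):
            r = np.linalg.norm(x, axis=-1, keepdims=True)
            return 0.3 * x * np.exp(-((r / 5.0) ** 2))

        f = field_factory(radial, shape=(16, 16, 16))
        rng = np.random.default_rng(6)
        img = VolumeImage(data=rng.random((16, 16, 16)), affine=f.affine)
        a = warp_by_inverse_chain(img, [f], tol=1e-4)
        b = warp_image(img, invert_field(f, tol=1e-4))
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_two_translations_compose_to_sum(self, field_factory):
        t1, t2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        fs = [
            field_factory(
                lambda x, t=t: np.broadcast_to(t, x.shape).copy(),
                shape=(16, 16, 16),
            )
            for t in (t1, t2)
        ]
        img = VolumeImage(data=np.zeros((16, 16, 16)), affine=fs[0].affine)
        img.data[8, 8, 8] = 1.0
        out = warp_by_inverse_chain(img, fs, tol=1e-6)
        # inverse of +t warps the feature by +t in index space
        assert out.data[9, 9, 8] == pytest.approx(1.0, abs=1e-3)

    def test_empty_chain_is_identity(self, field_factory):
        img = VolumeImage(data=np.ones((6, 6, 6)), affine=np.eye(4))
        out = warp_by_inverse_chain(img, [])
        np.testing.assert_array_equal(out.data, img.data)


class TestJacobianMap:
    def test_zero_field_gives_unit_jacobian(self, field_factory):
        f = field_factory(lambda x: np.zeros_like(x))
        np.testing.assert_allclose(field_jacobian_map(f).data, 1.0)

    def test_linear_field_matches_closed_form(self, field_factory):
        A = np.array([[0.05, 0.1, 0.0], [0.0, -0.04, 0.02], [0.01, 0.0, 0.08]])
        f = field_factory(lambda x: x @ A.T, shape=(10, 10, 10))
        expected = np.linalg.det(np.eye(3) + A)
        J = field_jacobian_map(f).data
        np.testing.assert_allclose(J, expected, atol=1e-6)

    def test_isotropic_scaling_cubes(self, field_factory):
        f = field_factory(lambda x: 0.1 * x, shape=(10, 10, 10))
        J = field_jacobian_map(f).data
        np.testing.assert_allclose(J[1:-1, 1:-1, 1:-1], 1.1**3, atol=1e-9)


class TestFieldIO:
    def test_round_trip(self, tmp_path, field_factory):
        f = field_factory(lambda x: np.sin(x / 3.0), tag="g_demo")
        p = tmp_path / "f.nii.gz"
        write_field(f, p)
        back = read_field(p)
        np.testing.assert_allclose(back.vectors, f.vectors, atol=1e-6)
        np.testing.assert_allclose(back.affine, f.affine, atol=1e-6)

    def test_voxel_dialect_scales_by_spacing(self, tmp_path, field_factory):
        f = field_factory(
            lambda x: np.ones_like(x), shape=(8, 8, 8), spacing=2.0
        )
        p = tmp_path / "vox.nii.gz"
        write_field(f, p)
        baseline = f.grid()
        mm = load_external_field(p, baseline, dialect="mm")
        vox = load_external_field(p, baseline, dialect="voxel")
        np.testing.assert_allclose(vox.vectors, 2.0 * mm.vectors)

    def test_wrong_component_count_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)),
            str(tmp_path / "bad.nii"),
        )
        from headmorph.imagevol import FormatError

        with pytest.raises(FormatError):
            read_field(tmp_path / "bad.nii")

    def test_mismatched_grid_resampled_on_load(self, tmp_path, field_factory):
        f = field_factory(
            lambda x: np.broadcast_to([1.0, 2.0, 3.0], x.shape).copy(),
            shape=(16, 16, 16),
        )
        p = tmp_path / "f.nii.gz"
        write_field(f, p)
        aff = np.eye(4)
        aff[:3, 3] = -4.0
        baseline = VolumeImage(data=np.zeros((9, 9, 9)), affine=aff)
        out = load_external_field(p, baseline)
        assert out.shape == (9, 9, 9)
        np.testing.assert_allclose(out.vectors[4, 4, 4], [1.0, 2.0, 3.0])


def test_zero_field_helper_matches_reference_grid(unit_grid):
    z = zero_field(unit_grid)
    assert z.shape == unit_grid.shape
    np.testing.assert_array_equal(z.vectors, 0.0)
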