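"""Rigid pre-alignment and diffeomorphic Demons registration of binary masks.

Each "feature step" of a personalization pipeline registers one segmented
binary mask of the subject (moving) to the matching mask of the baseline
(fixed). Raw binary images have degenerate gradients, so the masks are first
turned into signed distance maps and the Demons forces act on those; the
diffeomorphic (stationary-velocity, scaling-and-squaring) variant keeps the
resulting field non-folding, which the mesh-morphing step depends on.

The Demons solver itself is SimpleITK's DiffeomorphicDemonsRegistrationFilter
wrapped in a hand-built multi-resolution pyramid; this module owns the mask
preprocessing, the grid/affine conventions, and the moving/fixed bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .dispfield import (
    DisplacementField,
    field_jacobian_map,
    warp_by_inverse_chain,
    warp_image,
)
from .imagevol import EmptyMaskError, LabelMask, VolumeImage

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t in world mm."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(
            self.rotation @ self.rotation.T, np.eye(3), atol=1e-6
        ) or not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper orthonormal")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def resample_mask(self, mask: LabelMask, ref: VolumeImage) -> LabelMask:
        """Mask moved by this transform, sampled on ``ref``'s grid."""
        inv = self.inverse()
        pts = ref.grid_world_coords()
        src_pts = inv.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        idx = mask.world_to_voxel(src_pts)
        data = ndimage.map_coordinates(
            mask.data.astype(float),
            np.moveaxis(idx, -1, 0),
            order=0,
            mode="constant",
            cval=0.0,
        )
        return LabelMask(
            data=np.rint(data).astype(mask.data.dtype),
            affine=ref.affine.copy(),
            labels=dict(mask.labels),
        )


@dataclass
class DemonsParams:
    """Settings of one Demons mask-registration step.

    ``update_sigma_mm`` / ``field_sigma_mm`` are the Gaussian smoothing
    scales (mm) applied to the velocity update and to the accumulated field;
    ``None`` means 1 and 1.5 voxels of the fixed grid respectively.
    ``distance_cap_mm`` clamps the signed distance maps so far-field
    gradients do not dominate the forces.

    With ``localize`` the returned field is tapered smoothly to zero beyond
    ``support_cap_mm`` + ``support_taper_mm`` (mm) outside the union of the
    two masks: a mask constrains the transform only near its boundary, and
    the diffuse far-field tail that per-iteration field smoothing would
    otherwise leave behind corrupts the composition of later feature steps.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (50, 30, 20)
    update_sigma_mm: float | None = None
    field_sigma_mm: float | None = None
    step_scale: float = 1.0
    convergence_tol: float = 1e-4
    distance_cap_mm: float = 20.0
    localize: bool = True
    support_cap_mm: float = 15.0
    support_taper_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.iterations) != self.levels:
            raise ValueError("need one iteration count per pyramid level")
        for s in (self.update_sigma_mm, self.field_sigma_mm):
            if s is not None and s < 0:
                raise ValueError("smoothing sigmas must be >= 0")


def _mask_moments(mask: LabelMask) -> tuple[np.ndarray, np.ndarray]:
    """Centroid (mm) and principal-axis matrix (columns) of a binary mask."""
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    pts = mask.voxel_to_world(idx.astype(float))
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T) if len(pts) > 1 else np.eye(3)
    w, v = np.linalg.eigh(np.atleast_2d(cov) if cov.shape == (3, 3) else np.eye(3))
    order = np.argsort(w)[::-1]
    return c, v[:, order]


def _overlap(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / max(a.sum() + b.sum(), 1)


def rigid_align(moving: LabelMask, fixed: LabelMask) -> RigidTransform:
    """Centroid + principal-axes rigid transform taking moving onto fixed.

    Principal axes leave a 4-fold proper-rotation sign ambiguity; all four
    candidates are tried and the one maximizing mask overlap is kept.
    """
    cm, vm = _mask_moments(moving)
    cf, vf = _mask_moments(fixed)
    best: tuple[float, RigidTransform] | None = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.diag([sx, sy, sx * sy])  # keeps det = +1
        rot = vf @ signs @ vm.T
        if np.linalg.det(rot) < 0:  # eigh may return improper axes
            rot = vf @ (signs @ np.diag([1, 1, -1])) @ vm.T
        t = cf - rot @ cm
        cand = RigidTransform(rotation=rot, translation=t)
        moved = cand.resample_mask(moving, fixed)
        score = _overlap(moved.data > 0, fixed.data > 0)
        if best is None or score > best[0]:
            best = (score, cand)
    assert best is not None
    return best[1]


# --- SimpleITK conversion helpers -------------------------------------------

def _to_sitk(data: np.ndarray, affine: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T.astype(np.float64)))
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(affine[:3, 3]))
    img.SetDirection(tuple((lin / spacing).ravel()))
    return img


def _field_from_sitk(field: sitk.Image) -> np.ndarray:
    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3), world components
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)))


def _signed_distance(mask: LabelMask, cap_mm: float) -> sitk.Image:
    img = _to_sitk((mask.data > 0).astype(np.uint8), mask.affine)
    dist = sitk.SignedMaurerDistanceMap(
        sitk.Cast(img, sitk.sitkUInt8),
        insideIsPositive=False,
        squaredDistance=False,
        useImageSpacing=True,
    )
    return sitk.Clamp(dist, sitk.sitkFloat64, -cap_mm, cap_mm)


def demons_register(
    moving: LabelMask,
    fixed: LabelMask,
    params: DemonsParams | None = None,
    level_history: list | None = None,
) -> DisplacementField:
    """Multi-resolution diffeomorphic Demons between two binary masks.

    Returns a field u on the fixed grid with moving(x + u(x)) aligned to
    fixed(x); its Jacobian map is positive by construction of the
    exponentiated velocity updates. When a list is passed as
    ``level_history`` the post-level mask mismatch (1 - overlap after
    warping at full resolution) is appended per pyramid level.
    """
    params = params or DemonsParams()
    if not (moving.data > 0).any() or not (fixed.data > 0).any():
        raise EmptyMaskError("demons_register requires non-empty masks")
    if not np.logical_and(moving.data > 0, fixed.data > 0).any():
        raise RegistrationError(
            "masks do not overlap at all — review the rigid pre-alignment"
        )
    spacing = fixed.spacing
    upd_sigma = (
        params.update_sigma_mm
        if params.update_sigma_mm is not None
        else float(spacing.mean())
    )
    fld_sigma = (
        params.field_sigma_mm
        if params.field_sigma_mm is not None
        else 1.5 * float(spacing.mean())
    )
    mov = _signed_distance(moving, params.distance_cap_mm)
    fix = _signed_distance(fixed, params.distance_cap_mm)

    field: sitk.Image | None = None
    for level in range(params.levels):
        shrink = 2 ** (params.levels - 1 - level)
        if shrink > 1:
            sigma = [0.5 * shrink * s for s in spacing]
            fix_l = sitk.Shrink(
                sitk.SmoothingRecursiveGaussian(fix, sigma), [shrink] * 3
            )
            mov_l = sitk.Shrink(
                sitk.SmoothingRecursiveGaussian(mov, sigma), [shrink] * 3
            )
        else:
            fix_l, mov_l = fix, mov
        lvl_spacing = np.array(fix_l.GetSpacing())
        dem = sitk.DiffeomorphicDemonsRegistrationFilter()
        dem.SetNumberOfIterations(int(params.iterations[level]))
        dem.SetSmoothDisplacementField(True)
        dem.SetStandardDeviations(
            [max(fld_sigma / s, 1e-3) for s in lvl_spacing]
        )
        dem.SetSmoothUpdateField(True)
        dem.SetUpdateFieldStandardDeviations(
            [max(upd_sigma / s, 1e-3) for s in lvl_spacing]
        )
        dem.SetMaximumUpdateStepLength(2.0 * params.step_scale)
        dem.SetIntensityDifferenceThreshold(params.convergence_tol)
        if field is None:
            field = dem.Execute(fix_l, mov_l)
        else:
            init = sitk.Resample(
                field,
                fix_l,
                sitk.Transform(),
                sitk.sitkLinear,
                0.0,
                sitk.sitkVectorFloat64,
            )
            field = dem.Execute(fix_l, mov_l, init)
        log.info(
            "demons level %d (shrink %d): RMS change %.4g",
            level,
            shrink,
            dem.GetRMSChange(),
        )
        if level_history is not None:
            full = sitk.Resample(
                field,
                _to_sitk(fixed.data.astype(float), fixed.affine),
                sitk.Transform(),
                sitk.sitkLinear,
                0.0,
                sitk.sitkVectorFloat64,
            )
            f_lvl = DisplacementField(
                vectors=_field_from_sitk(full), affine=fixed.affine.copy()
            )
            warped = warp_image(moving, f_lvl, interp="nearest")
            level_history.append(1.0 - _overlap(warped.data > 0, fixed.data > 0))
    assert field is not None
    if field.GetSize() != tuple(fixed.shape):
        field = sitk.Resample(
            field,
            _to_sitk(fixed.data.astype(float), fixed.affine),
            sitk.Transform(),
            sitk.sitkLinear,
            0.0,
            sitk.sitkVectorFloat64,
        )
    vectors = _field_from_sitk(field)
    if params.localize:
        union = (moving.data > 0) | (fixed.data > 0)
        d = ndimage.distance_transform_edt(~union, sampling=fixed.spacing)
        t = np.clip(
            (d - params.support_cap_mm) / params.support_taper_mm, 0.0, 1.0
        )
        vectors = vectors * ((1.0 - t * t) ** 2)[..., None]
    out = DisplacementField(
        vectors=vectors,
        affine=fixed.affine.copy(),
        tag="demons",
    )
    jmin = float(field_jacobian_map(out).data[1:-1, 1:-1, 1:-1].min())
    if jmin <= 0:
        log.warning("demons field has non-positive interior Jacobian (%.3g)", jmin)
    return out


def register_feature_sequence(
    features: list[tuple[LabelMask, LabelMask]],
    params: DemonsParams | None = None,
) -> list[DisplacementField]:
    """Run one Demons step per (moving, fixed) feature pair, hierarchically.

    Before each step the fixed-side (baseline) mask is warped by the inverse
    chain of the fields already accumulated, so later features are registered
    against the progressively personalized baseline. Returns the per-step
    fields in order, ready for summation.
    """
    fields: list[DisplacementField] = []
    for i, (mov, fix) in enumerate(features):
        fix_w = (
            warp_by_inverse_chain(fix, fields, interp="nearest")
            if fields
            else fix
        )
        f = demons_register(mov, fix_w, params)
        f.tag = f"g_f{i}" if i else "g_demo"
        fields.append(f)
    return fields
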