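"""Dense displacement-field algebra.

A displacement field u assigns each point x of the fixed (baseline) grid a
world-mm vector such that the corresponding point in the moving image is
x + u(x). The pipeline sums per-step fields to morph the mesh, and warps the
baseline image through the *nested inverse chain* of the same steps to score
accuracy — the two composition rules are deliberately kept distinct (the sum
approximates the composition only for small or disjoint-support fields).

All fields are stored voxelwise on a stated reference grid, vectors in world
mm, with a provenance tag naming the registration step (g_demo, g_f1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .imagevol import FormatError, LabelMask, VolumeImage, _check_affine


class InversionError(RuntimeError):
    """Fixed-point inversion failed to reach the requested residual."""


@dataclass
class DisplacementField:
    """Per-voxel 3-vector (mm) on a reference grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    affine: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.vectors.shape[:3])  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def grid(self) -> VolumeImage:
        """The reference grid as an (empty) volume, for resampling targets."""
        return VolumeImage(
            data=np.zeros(self.shape), affine=self.affine.copy()
        )

    def same_grid(self, other: "DisplacementField | VolumeImage") -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


def zero_field(ref: VolumeImage, tag: str = "zero") -> DisplacementField:
    return DisplacementField(
        vectors=np.zeros(ref.shape + (3,)), affine=ref.affine.copy(), tag=tag
    )


def sample_field(f: DisplacementField, pts: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated displacement (mm) at world points ``pts``.

    ``pts`` has shape ``(..., 3)``; the result matches. Points outside the
    grid's support get the zero vector, so the function is total.
    """
    pts = np.asarray(pts, dtype=float)
    flat = pts.reshape(-1, 3)
    inv = np.linalg.inv(f.affine)
    idx = flat @ inv[:3, :3].T + inv[:3, 3]
    coords = idx.T  # (3, n)
    out = np.empty_like(flat)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            f.vectors[..., c], coords, order=1, mode="constant", cval=0.0
        )
    return out.reshape(pts.shape)


def sum_fields(fields: list[DisplacementField]) -> DisplacementField:
    """Voxelwise vector sum of per-step fields (all on one grid)."""
    if not fields:
        raise ValueError("sum_fields needs at least one field")
    first = fields[0]
    total = first.vectors.copy()
    for f in fields[1:]:
        if f.shape != first.shape or not np.allclose(
            f.affine, first.affine, atol=1e-6
        ):
            raise ValueError(
                f"field {f.tag!r} is not on the same grid as {first.tag!r}"
            )
        total += f.vectors
    tag = "+".join(f.tag or "?" for f in fields)
    return DisplacementField(vectors=total, affine=first.affine.copy(), tag=tag)


def field_jacobian_map(f: DisplacementField) -> VolumeImage:
    """Jacobian-determinant map det(I + grad u), gradient in world mm.

    Central differences in the interior, one-sided at the faces. Equals 1
    everywhere for the zero field; positivity everywhere is the usual
    non-folding check on a deformation.
    """
    ainv = np.linalg.inv(f.affine[:3, :3])
    grads = np.empty(f.shape + (3, 3))
    for c in range(3):
        # du_c/d(index axis a), then chain rule to world coordinates
        gi = np.stack(np.gradient(f.vectors[..., c]), axis=-1)  # (..., 3)
        grads[..., c, :] = gi @ ainv
    jac = np.linalg.det(np.eye(3) + grads)
    return VolumeImage(data=jac, affine=f.affine.copy(), modality="Jimg")


def invert_field(
    f: DisplacementField,
    tol: float = 0.05,
    max_iter: int = 50,
    strict: bool = False,
) -> DisplacementField:
    """Numerical inverse h of a displacement field f.

    Solves f(x + h(x)) + h(x) = 0 on the grid by fixed-point iteration
    h_{k+1}(x) = -f(x + h_k(x)), h_0 = -f, stopping when the max residual
    norm over interior grid points drops below ``tol`` (mm).

    With ``strict`` a non-positive Jacobian raises; otherwise it only means
    the iteration may not converge, which is then reported.
    """
    jmin = field_jacobian_map(f).data[1:-1, 1:-1, 1:-1]
    if jmin.size and jmin.min() <= 0:
        msg = (
            f"field {f.tag!r} has non-positive Jacobian "
            f"(min {jmin.min():.3g}); it is not invertible everywhere"
        )
        if strict:
            raise InversionError(msg)
    X = f.grid().grid_world_coords()
    h = -f.vectors
    interior = (slice(1, -1),) * 3
    residual = np.inf
    for _ in range(max_iter):
        fxh = sample_field(f, X + h)
        res = fxh + h
        residual = float(np.linalg.norm(res[interior], axis=-1).max())
        if residual <= tol:
            break
        h = -fxh
    else:
        raise InversionError(
            f"inversion of {f.tag!r} did not reach tol={tol} mm in "
            f"{max_iter} iterations (residual {residual:.4g} mm)"
        )
    return DisplacementField(
        vectors=h, affine=f.affine.copy(), tag=f"inv({f.tag})"
    )


def warp_image(
    img: VolumeImage, f: DisplacementField, interp: str = "linear"
) -> VolumeImage:
    """Pull-back warp: out(x) = img(x + f(x)) on f's grid.

    Label masks are warped with nearest-neighbour interpolation and keep
    their label table.
    """
    if isinstance(img, LabelMask):
        interp = "nearest"
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    ref = f.grid()
    pts = ref.grid_world_coords() + f.vectors
    idx = img.world_to_voxel(pts)
    coords = np.moveaxis(idx, -1, 0)
    order = 1 if interp == "linear" else 0
    data = ndimage.map_coordinates(
        img.data.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    if isinstance(img, LabelMask):
        return LabelMask(
            data=np.rint(data).astype(img.data.dtype),
            affine=f.affine.copy(),
            labels=dict(img.labels),
        )
    return VolumeImage(data=data, affine=f.affine.copy(), modality=img.modality)


def warp_by_inverse_chain(
    img: VolumeImage,
    fields: list[DisplacementField],
    interp: str = "linear",
    tol: float = 0.05,
    max_iter: int = 50,
) -> VolumeImage:
    """Warp an image through the inverses of an ordered step chain.

    ``fields`` is the pipeline's forward order (g_demo, g_f1, ..., g_fn); the
    first-registered step is applied innermost, i.e. the output is
    g_fn^-1(... g_f1^-1(g_demo^-1(img))). An empty chain returns the image
    unchanged.
    """
    out = img
    for f in fields:
        out = warp_image(out, invert_field(f, tol=tol, max_iter=max_iter), interp)
    return out


def write_field(f: DisplacementField, path: str | Path) -> None:
    """Store a field as 4D NIfTI, last axis = (x, y, z) components in mm."""
    nib.save(nib.Nifti1Image(f.vectors.astype(np.float32), f.affine), str(path))


def read_field(path: str | Path, tag: str = "") -> DisplacementField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 3-component vector volume, got shape {data.shape}"
        )
    return DisplacementField(
        vectors=np.asarray(data, dtype=float),
        affine=img.affine,
        tag=tag or Path(str(path)).stem,
    )


def load_external_field(
    path: str | Path,
    baseline: VolumeImage,
    dialect: str = "mm",
    tag: str = "",
) -> DisplacementField:
    """Adapter for fields produced by outside registration tools.

    ``dialect="mm"`` takes vectors as world mm; ``dialect="voxel"`` converts
    per-axis voxel displacements via the source grid spacing. The field is
    resampled onto the baseline grid if needed.
    """
    f = read_field(path, tag=tag)
    if dialect == "voxel":
        f = DisplacementField(
            vectors=f.vectors * f.spacing, affine=f.affine, tag=f.tag
        )
    elif dialect != "mm":
        raise ValueError(f"unknown field dialect {dialect!r}")
    return resample_field(f, baseline)


def resample_field(
    f: DisplacementField, ref: VolumeImage
) -> DisplacementField:
    """Resample a field's vectors onto ``ref``'s grid (components linear)."""
    if f.shape == ref.shape and np.allclose(f.affine, ref.affine, atol=1e-6):
        return f
    pts = ref.grid_world_coords()
    vec = sample_field(f, pts)
    return DisplacementField(vectors=vec, affine=ref.affine.copy(), tag=f.tag)
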