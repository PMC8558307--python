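"""Volumetric images and label masks on a 3D grid with a voxel-to-world map.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)``;
* world coordinates are millimetres, obtained from the NIfTI affine as
  ``x = A[:3, :3] @ (i, j, k) + A[:3, 3]``;
* every image that participates in a personalization pipeline lives on the
  *baseline* grid — use :func:`resample_to_grid` to bring foreign grids over;
* out-of-domain samples are zero, never NaN, so overlap metrics downstream
  stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input file does not parse as the expected format."""


class EmptyMaskError(ValueError):
    """Raised when an operation that needs foreground voxels finds none."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class VolumeImage:
    """A 3D scalar image: data array plus voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.affine = _check_affine(self.affine)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(..., 3)`` to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world-mm points ``(..., 3)`` to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"),
            axis=-1,
        ).astype(float)
        return self.voxel_to_world(idx)

    def same_grid(self, other: "VolumeImage", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class LabelMask(VolumeImage):
    """Integer-valued segmentation mask; 0 is background.

    ``labels`` maps label id -> region name (e.g. ``{1: "WM", 2: "LV"}``).
    """

    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if np.issubdtype(self.data.dtype, np.floating):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise FormatError("label mask contains non-integer values")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label mask contains negative labels")
        super().__post_init__()

    def binarize(self, label: int | None = None) -> "LabelMask":
        """Binary mask of one label (or of all foreground when None)."""
        fg = self.data > 0 if label is None else self.data == label
        return LabelMask(
            data=fg.astype(np.uint8), affine=self.affine, labels={1: "fg"}
        )

    def region(self, name: str) -> "LabelMask | None":
        """Binary mask for a named region; None if the name is unknown."""
        for lid, lname in self.labels.items():
            if lname == name:
                return self.binarize(lid)
        return None


def read_volume(path: str | Path, modality: str = "") -> VolumeImage:
    """Load a 3D NIfTI volume (``.nii`` / ``.nii.gz``)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, got {data.ndim} dimensions "
            f"(shape {data.shape})"
        )
    data = np.asarray(data, dtype=float)
    data[~np.isfinite(data)] = 0.0
    return VolumeImage(data=data, affine=img.affine, modality=modality)


def read_mask(path: str | Path, labels: dict[int, str] | None = None) -> LabelMask:
    """Load an integer NIfTI segmentation as a :class:`LabelMask`."""
    vol = read_volume(path)
    return LabelMask(data=vol.data, affine=vol.affine, labels=labels or {})


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume (or mask) to NIfTI; masks get an integer on-disk type."""
    if isinstance(vol, LabelMask):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def threshold_clean_mask(
    vol: VolumeImage, low: float, high: float = np.inf
) -> LabelMask:
    """Threshold an intensity image and remove noise.

    Noise removal keeps the largest 26-connected component of the
    thresholded set and fills its interior holes — the usual cleanup after
    intensity thresholding of a cranial mask.
    """
    if low > high:
        raise ValueError(f"low ({low}) must be <= high ({high})")
    raw = (vol.data >= low) & (vol.data <= high)
    if not raw.any():
        raise EmptyMaskError(
            f"threshold [{low}, {high}] selects no voxels"
        )
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    lab, n = ndimage.label(raw, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(raw, lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        raw = lab == keep
    raw = ndimage.binary_fill_holes(raw)
    return LabelMask(
        data=raw.astype(np.uint8), affine=vol.affine, labels={1: "fg"}
    )


def resample_to_grid(
    vol: VolumeImage, ref: VolumeImage, interp: str = "linear"
) -> VolumeImage:
    """Resample ``vol`` onto ``ref``'s grid.

    ``interp`` is ``"linear"`` or ``"nearest"``; label masks always use
    nearest regardless, so no labels are invented. Samples falling outside
    ``vol``'s domain are 0.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if isinstance(vol, LabelMask):
        interp = "nearest"
    if vol.same_grid(ref):
        out_data = vol.data.copy()
    else:
        pts = ref.grid_world_coords()
        idx = vol.world_to_voxel(pts)
        coords = np.moveaxis(idx, -1, 0)
        order = 1 if interp == "linear" else 0
        out_data = ndimage.map_coordinates(
            vol.data.astype(float), coords, order=order, mode="constant", cval=0.0
        )
    if isinstance(vol, LabelMask):
        return LabelMask(
            data=np.rint(out_data).astype(vol.data.dtype),
            affine=ref.affine.copy(),
            labels=dict(vol.labels),
        )
    return VolumeImage(
        data=out_data, affine=ref.affine.copy(), modality=vol.modality
    )


def like(vol: VolumeImage, data: np.ndarray) -> VolumeImage:
    """A new volume with ``data`` on ``vol``'s grid."""
    return replace(vol, data=data)
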