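"""Deterministic head phantoms: images, masks, meshes, ground-truth fields.

The phantom is a nested-ellipsoid head: a filled cranial ellipsoid (the
intracranial space), a brain ellipsoid inside it, a white-matter blob inside
the brain, and a ventricle-like cavity inside the white matter. "Subjects"
are produced by known smooth, invertible deformations of the baseline —
global size change, ventricle enlargement, a focal lesion bulge, or their
composite — spanning the same qualitative spectrum as real heads from
newborn to hydrocephalus. Because the deforming fields are closed-form,
registration and morphing accuracy can be scored exactly.

Everything is deterministic given the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .dispfield import DisplacementField, field_jacobian_map, invert_field, warp_image
from .grouping import regroup_elements
from .hexmesh import HexMesh, scaled_jacobian
from .imagevol import LabelMask, VolumeImage

TISSUE_LABELS = {1: "GM", 2: "WM", 3: "LV"}


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Geometry, grid and deformation parameters of one phantom.

    Lengths are mm. The default grid (64^3 voxels at 2 mm) keeps every
    end-to-end run desk-sized. ``deformation`` is one of ``none``,
    ``global_scale``, ``ventricle_enlarge``, ``lesion_bulge`` or
    ``composite``; magnitudes have defaults chosen to stay well inside the
    positive-Jacobian bound (checked numerically at construction).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.0
    cranial_radii: tuple[float, float, float] = (52.0, 44.0, 40.0)
    brain_radii: tuple[float, float, float] = (46.0, 38.0, 34.0)
    wm_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    wm_radii: tuple[float, float, float] = (30.0, 25.0, 22.0)
    ventricle_center: tuple[float, float, float] = (0.0, 2.0, 2.0)
    ventricle_radii: tuple[float, float, float] = (8.0, 13.0, 9.0)
    deformation: str = "none"
    scale: float = 0.1  # fractional global size change
    ventricle_factor: float = 3.0  # ventricle volume multiplier
    ventricle_support: float = 2.6  # bump support in ventricle radii
    lesion_center: tuple[float, float, float] = (0.0, -38.0, 0.0)
    lesion_radius: float = 16.0
    lesion_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)
    lesion_magnitude: float = 3.0  # mm outward push
    noise_sigma: float = 2.0  # intensity noise std
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation not in (
            "none", "global_scale", "ventricle_enlarge", "lesion_bulge", "composite"
        ):
            raise PhantomSpecError(f"unknown deformation {self.deformation!r}")
        # strict nesting: ventricle < wm < brain < cranial
        vc = np.asarray(self.ventricle_center)
        wc = np.asarray(self.wm_center)
        for inner_c, inner_r, outer_c, outer_r, what in (
            (vc, self.ventricle_radii, wc, self.wm_radii, "ventricle in WM"),
            (wc, self.wm_radii, np.zeros(3), self.brain_radii, "WM in brain"),
            (np.zeros(3), self.brain_radii, np.zeros(3), self.cranial_radii,
             "brain in cranial"),
        ):
            # inner surface point furthest out along each axis must stay inside
            extent = np.abs(inner_c - outer_c) + np.asarray(inner_r)
            if np.any(extent >= np.asarray(outer_r)):
                raise PhantomSpecError(f"nesting violated: {what}")

    def grid_affine(self) -> np.ndarray:
        """Axis-aligned affine with the world origin at the grid centre."""
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = -self.spacing * (np.asarray(self.shape) - 1) / 2.0
        return aff


@dataclass
class Phantom:
    """A generated phantom: intensity image plus its binary region masks."""

    image: VolumeImage
    masks: dict[str, LabelMask]  # cranial, brain, wm, ventricle (binary)
    tissue: LabelMask  # combined GM/WM/LV label mask
    spec: PhantomSpec | None = None


def _ellipsoid(
    coords: np.ndarray, center: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    r = (coords - center) / radii
    return (r * r).sum(axis=-1) <= 1.0


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Baseline phantom image + masks on the spec's grid."""
    spec = spec or PhantomSpec()
    affine = spec.grid_affine()
    ref = VolumeImage(data=np.zeros(spec.shape), affine=affine)
    xyz = ref.grid_world_coords()

    cranial = _ellipsoid(xyz, np.zeros(3), np.asarray(spec.cranial_radii))
    brain = _ellipsoid(xyz, np.zeros(3), np.asarray(spec.brain_radii))
    wm = _ellipsoid(xyz, np.asarray(spec.wm_center), np.asarray(spec.wm_radii))
    vent = _ellipsoid(
        xyz, np.asarray(spec.ventricle_center), np.asarray(spec.ventricle_radii)
    )

    tissue = np.zeros(spec.shape, dtype=np.int16)
    tissue[brain] = 1  # GM
    tissue[wm & brain] = 2  # WM
    tissue[vent] = 3  # LV (ventricular CSF cavity)

    # T1-like contrast: bone-adjacent CSF dark-ish, GM mid, WM bright, LV dark
    intensity = np.zeros(spec.shape)
    intensity[cranial] = 30.0
    intensity[tissue == 1] = 70.0
    intensity[tissue == 2] = 100.0
    intensity[tissue == 3] = 20.0
    intensity = ndimage.gaussian_filter(intensity, sigma=1.0)
    rng = np.random.default_rng(spec.seed)
    intensity = np.clip(
        intensity + rng.normal(0.0, spec.noise_sigma, spec.shape), 0.0, None
    )

    def mask(arr: np.ndarray, name: str) -> LabelMask:
        return LabelMask(
            data=arr.astype(np.uint8), affine=affine.copy(), labels={1: name}
        )

    return Phantom(
        image=VolumeImage(data=intensity, affine=affine.copy(), modality="T1W"),
        masks={
            "cranial": mask(cranial, "cranial"),
            "brain": mask(brain, "brain"),
            "wm": mask(wm & brain, "wm"),
            "ventricle": mask(vent, "ventricle"),
        },
        tissue=LabelMask(
            data=tissue, affine=affine.copy(), labels=dict(TISSUE_LABELS)
        ),
        spec=spec,
    )


# --------------------------------------------------------------------------
# closed-form ground-truth deformations


def _radial_bump(
    xyz: np.ndarray,
    center: np.ndarray,
    radii: np.ndarray,
    amplitude: float,
    support: float,
) -> np.ndarray:
    """u(x) = a(r) (x - c) with a C1 compact bump in normalized radius."""
    d = xyz - center
    r = np.linalg.norm(d / radii, axis=-1)
    t = np.clip(r / support, 0.0, 1.0)
    a = amplitude * (1.0 - t * t) ** 2
    return a[..., None] * d


def _directional_bump(
    xyz: np.ndarray,
    center: np.ndarray,
    radius: float,
    direction: np.ndarray,
    magnitude: float,
) -> np.ndarray:
    d = np.linalg.norm(xyz - center, axis=-1)
    t = np.clip(d / radius, 0.0, 1.0)
    w = magnitude * (1.0 - t * t) ** 2
    dirn = direction / np.linalg.norm(direction)
    return w[..., None] * dirn


def analytic_deformation(spec: PhantomSpec) -> DisplacementField:
    """Ground-truth smooth invertible field for the spec's deformation kind.

    The field maps baseline points to subject points, x -> x + u(x); its
    Jacobian map is verified strictly positive at construction.
    """
    affine = spec.grid_affine()
    ref = VolumeImage(data=np.zeros(spec.shape), affine=affine)
    xyz = ref.grid_world_coords()
    u = np.zeros(spec.shape + (3,))

    def add_scale() -> None:
        nonlocal u
        u = u + spec.scale * xyz

    def add_ventricle() -> None:
        nonlocal u
        lin = spec.ventricle_factor ** (1.0 / 3.0) - 1.0
        s = spec.ventricle_support
        amp = lin / (1.0 - 1.0 / (s * s)) ** 2  # a(1) = lin at the surface
        u = u + _radial_bump(
            xyz,
            np.asarray(spec.ventricle_center),
            np.asarray(spec.ventricle_radii),
            amp,
            s,
        )

    def add_lesion() -> None:
        nonlocal u
        u = u + _directional_bump(
            xyz,
            np.asarray(spec.lesion_center),
            spec.lesion_radius,
            np.asarray(spec.lesion_direction),
            spec.lesion_magnitude,
        )

    if spec.deformation == "global_scale":
        add_scale()
    elif spec.deformation == "ventricle_enlarge":
        add_ventricle()
    elif spec.deformation == "lesion_bulge":
        add_lesion()
    elif spec.deformation == "composite":
        add_scale()
        add_ventricle()
        add_lesion()

    f = DisplacementField(vectors=u, affine=affine, tag=f"g*_{spec.deformation}")
    jmin = float(field_jacobian_map(f).data[1:-1, 1:-1, 1:-1].min())
    if spec.deformation != "none" and jmin <= 0.0:
        raise PhantomSpecError(
            f"deformation parameters exceed the positive-Jacobian bound "
            f"(min J_img = {jmin:.3f})"
        )
    return f


def deform_phantom(
    phantom: Phantom, field: DisplacementField, tol: float = 0.02
) -> Phantom:
    """Subject phantom: the baseline pushed through an invertible field.

    The subject image at y equals the baseline at the preimage of y, i.e.
    everything is warped by the numerical inverse of ``field``.
    """
    inv = invert_field(field, tol=tol, max_iter=100)
    return Phantom(
        image=warp_image(phantom.image, inv, interp="linear"),
        masks={k: warp_image(m, inv) for k, m in phantom.masks.items()},
        tissue=warp_image(phantom.tissue, inv),
        spec=phantom.spec,
    )


def make_subject(
    spec: PhantomSpec,
) -> tuple[Phantom, Phantom, DisplacementField]:
    """Convenience: (baseline, deformed subject, ground-truth field)."""
    base = make_phantom(spec)
    g = analytic_deformation(spec)
    subj = deform_phantom(base, g)
    return base, subj, g


# --------------------------------------------------------------------------
# structured hexahedral baseline mesh


def _rounded_cube_map(p: np.ndarray, sphericity: float = 0.6) -> np.ndarray:
    """Smooth map of [-1, 1]^3 into the unit ball with bounded distortion.

    Blends the identity with the radial cube-shell-to-sphere-shell map,
    increasingly toward the boundary but never fully (a fully spherified
    cube degenerates the corner elements); the image is then uniformly
    shrunk to fit inside the unit ball. ``sphericity`` = 0.6 keeps every
    element of a 16^3 lattice above scaled Jacobian 0.75.
    """
    m = np.abs(p).max(axis=-1)
    r2 = np.linalg.norm(p, axis=-1)
    safe = np.where(r2 > 0, r2, 1.0)
    radial = p * (m / safe)[..., None]
    a = (sphericity * m)[..., None]
    q = (1 - a) * p + a * radial
    corner_reach = np.sqrt(3.0) * (1 - sphericity) + sphericity
    return q / corner_reach


def make_baseline_hexmesh(
    spec: PhantomSpec | None = None,
    n: int = 16,
    fill: float = 0.97,
    assign_parts: bool = True,
) -> HexMesh:
    """Structured n^3-element all-hex mesh filling the brain ellipsoid.

    A uniform lattice on the cube is pushed through a smooth cube-to-ball
    map and scaled by the brain semi-axes; element parts (GM/WM/LV) are then
    assigned from the phantom's tissue mask by voxel-weight regrouping. The
    construction keeps every element's scaled Jacobian >= 0.5.
    """
    spec = spec or PhantomSpec()
    min_vent = 2.0 * min(spec.ventricle_radii)
    elem_size = 2.0 * min(spec.brain_radii) * fill / n
    if min_vent / elem_size < 2.0:
        raise PhantomSpecError(
            f"{n}^3 elements are too coarse to represent the ventricle "
            f"({min_vent / elem_size:.1f} elements across, need >= 2)"
        )
    lin = np.linspace(-1.0, 1.0, n + 1)
    p = np.stack(np.meshgrid(lin, lin, lin, indexing="ij"), axis=-1)
    ball = _rounded_cube_map(p) * (np.asarray(spec.brain_radii) * fill)
    nodes = ball.reshape(-1, 3)

    nid = np.arange((n + 1) ** 3).reshape(n + 1, n + 1, n + 1)
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    elements = np.stack(
        [
            nid[i, j, k], nid[i + 1, j, k], nid[i + 1, j + 1, k], nid[i, j + 1, k],
            nid[i, j, k + 1], nid[i + 1, j, k + 1], nid[i + 1, j + 1, k + 1],
            nid[i, j + 1, k + 1],
        ],
        axis=-1,
    ).reshape(-1, 8)
    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        parts=np.array(["GM"] * len(elements), dtype=object),
    )
    sj = np.asarray(scaled_jacobian(mesh))
    if sj.min() < 0.5:
        raise PhantomSpecError(
            f"constructed mesh violates the quality bound (min SJ {sj.min():.3f})"
        )
    if assign_parts:
        phantom = make_phantom(spec)
        mesh = regroup_elements(
            mesh, phantom.tissue, parts_in_play={"GM", "WM", "LV"}
        )
    return mesh
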