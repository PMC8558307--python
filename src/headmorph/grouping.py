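"""Voxel-weighted regrouping of morphed brain elements.

After morphing, the white-matter part of the brain mesh is reassigned from
the subject's segmented WM image: for every eligible element, each candidate
voxel contributes a weight equal to the number of its 8 vertices falling
inside the element plus 2 if its centroid does (max 10); weights are summed
per label (background included) and the element takes the argmax label,
keeping its prior part on ties or when nothing falls inside.

The inside test inverts the trilinear isoparametric map of the hexahedron
by Newton iteration; a 24-tetrahedra decomposition serves as the
independent oracle in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hexmesh import HexMesh
from .imagevol import LabelMask

log = logging.getLogger(__name__)

# local corner signs of the reference hex [-1, 1]^3, standard brick ordering
_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)

_BOUNDARY_TOL = 1e-9
_CHUNK = 200_000  # probe points per Newton batch; bounds peak memory


@dataclass(frozen=True)
class VoxelWeight:
    """Weight of one voxel with respect to one element (0-10)."""

    index: tuple[int, int, int]
    weight: int


def _shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions, xi (..., 3) -> (..., 8)."""
    terms = 1.0 + xi[..., None, :] * _XI  # (..., 8, 3)
    return terms.prod(axis=-1) / 8.0


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi, shape (..., 8, 3)."""
    t = 1.0 + xi[..., None, :] * _XI  # (..., 8, 3)
    grad = np.empty(t.shape)
    grad[..., 0] = _XI[:, 0] * t[..., 1] * t[..., 2]
    grad[..., 1] = _XI[:, 1] * t[..., 0] * t[..., 2]
    grad[..., 2] = _XI[:, 2] * t[..., 0] * t[..., 1]
    return grad / 8.0


def _newton_xi(
    corners: np.ndarray,
    pts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the isoparametric map; one element's corners per point.

    ``corners`` is (n, 8, 3), ``pts`` is (n, 3). Returns (xi, converged).
    """
    n = len(pts)
    xi = np.zeros((n, 3))
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        xa = xi[idx]
        ca = corners[idx]
        r = np.einsum("pa,paj->pj", _shape_functions(xa), ca) - pts[idx]
        done = np.linalg.norm(r, axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
        still = idx[~done]
        if still.size == 0:
            continue
        xa = xi[still]
        # J[p, j, i] = d x_j / d xi_i
        J = np.einsum("pai,paj->pji", _shape_gradients(xa), corners[still])
        rs = r[~done]
        ok = np.abs(np.linalg.det(J)) > 1e-14
        if not ok.all():
            active[still[~ok]] = False  # singular: treated as outside
            still = still[ok]
            J = J[ok]
            rs = rs[ok]
            xa = xa[ok]
            if still.size == 0:
                continue
        dxi = np.linalg.solve(J, rs[..., None])[..., 0]
        xi[still] = np.clip(xa - dxi, -8.0, 8.0)  # keep Newton from flying off
        # a stalled step means a (clipped) fixed point that is not a root:
        # drop it from the active set, it will count as outside
        stalled = np.linalg.norm(dxi, axis=1) < 1e-12
        active[still[stalled]] = False
    return xi, converged


def local_coordinates(
    corners: np.ndarray,
    pts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Local coordinates of many points within one element."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    rep = np.broadcast_to(corners, (len(pts), 8, 3))
    return _newton_xi(rep, pts, tol=tol, max_iter=max_iter)


def points_in_hex(mesh: HexMesh, elem: int, pts: np.ndarray) -> np.ndarray:
    """Vectorised inside test for many world points against one element.

    A point is inside iff the Newton inversion converges with every local
    coordinate in [-1, 1] (boundary counts as inside within 1e-9).
    """
    corners = mesh.element_corners(elem)[0]
    xi, conv = local_coordinates(corners, pts)
    inside = conv & np.all(np.abs(xi) <= 1.0 + _BOUNDARY_TOL, axis=1)
    n_bad = int(np.count_nonzero(~conv))
    if n_bad:
        log.debug("element %d: %d points failed Newton, counted outside", elem, n_bad)
    return inside


def point_in_hex(mesh: HexMesh, elem: int, p: np.ndarray) -> bool:
    """Scalar convenience wrapper around :func:`points_in_hex`."""
    return bool(points_in_hex(mesh, elem, np.atleast_2d(p))[0])


def _voxel_probe_points(
    mask: LabelMask, vox_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """World coordinates of the 8 vertices and centroid of each voxel.

    Returns (vertices (n, 8, 3), centroids (n, 3)). A voxel (i, j, k) spans
    the index cube of half-width 1/2 around its centre.
    """
    offs = _XI * 0.5  # corner offsets in index space
    vert_idx = vox_idx[:, None, :] + offs[None, :, :]
    verts = mask.voxel_to_world(vert_idx)
    cents = mask.voxel_to_world(vox_idx.astype(float))
    return verts, cents


def _candidate_voxels(mesh: HexMesh, elem: int, mask: LabelMask) -> np.ndarray:
    """Voxel indices whose cube may intersect the element (bbox prefilter)."""
    corners = mesh.element_corners(elem)[0]
    idx = mask.world_to_voxel(corners)
    lo = np.maximum(np.floor(idx.min(axis=0) - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil(idx.max(axis=0) + 0.5).astype(int), np.array(mask.shape) - 1
    )
    if np.any(hi < lo):
        return np.empty((0, 3), dtype=int)
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)


def _pair_weights(
    mesh: HexMesh, elem_of_pair: np.ndarray, vox_of_pair: np.ndarray, mask: LabelMask
) -> np.ndarray:
    """Voxel weight for each (element, voxel) candidate pair, chunked."""
    n = len(elem_of_pair)
    weights = np.zeros(n, dtype=np.int64)
    pair_chunk = max(_CHUNK // 9, 1)
    for s in range(0, n, pair_chunk):
        e = elem_of_pair[s: s + pair_chunk]
        v = vox_of_pair[s: s + pair_chunk]
        verts, cents = _voxel_probe_points(mask, v)
        pts = np.concatenate([verts.reshape(-1, 3), cents], axis=0)
        corners = mesh.element_corners()[e]  # (m, 8, 3)
        corner_rep = np.concatenate(
            [np.repeat(corners, 8, axis=0), corners], axis=0
        )
        xi, conv = _newton_xi(corner_rep, pts)
        inside = conv & np.all(np.abs(xi) <= 1.0 + _BOUNDARY_TOL, axis=1)
        m = len(e)
        v_in = inside[: 8 * m].reshape(m, 8).sum(axis=1)
        c_in = inside[8 * m:]
        weights[s: s + pair_chunk] = v_in + 2 * c_in
    return weights


def element_voxel_weights(
    mesh: HexMesh, elem: int, mask: LabelMask
) -> list[VoxelWeight]:
    """Per-voxel weights of all mask voxels touching one element.

    Weight = (# of the voxel's 8 vertices inside) + 2 * (centroid inside);
    voxels with zero weight are omitted.
    """
    vox = _candidate_voxels(mesh, elem, mask)
    if len(vox) == 0:
        return []
    w = _pair_weights(
        mesh, np.full(len(vox), elem, dtype=np.int64), vox, mask
    )
    return [
        VoxelWeight(index=tuple(int(x) for x in vox[i]), weight=int(w[i]))
        for i in range(len(vox))
        if w[i] > 0
    ]


def regroup_elements(
    mesh: HexMesh,
    mask: LabelMask,
    parts_in_play: set[str] | list[str],
    target_map: dict[int, str] | None = None,
    include_background: bool = True,
) -> HexMesh:
    """Reassign eligible elements to the mask label with the largest weight.

    ``parts_in_play`` names the element parts eligible for relabeling
    (typically the brain tissues competing with WM). ``target_map`` maps
    mask label ids to part names; by default the mask's own label table is
    used. Background (label 0) competes in the argmax so that an element
    mostly outside the mask's foreground keeps its prior part; ties and
    zero-weight elements keep the prior part as well.
    """
    eligible = set(parts_in_play)
    tmap = dict(target_map or mask.labels)
    elig_ids = np.flatnonzero(np.isin(mesh.parts, list(eligible)))
    if elig_ids.size == 0:
        return mesh.with_parts(mesh.parts.copy())

    # gather all candidate (element, voxel) pairs, then weight them in bulk
    elem_of_pair: list[np.ndarray] = []
    vox_of_pair: list[np.ndarray] = []
    for e in elig_ids:
        vox = _candidate_voxels(mesh, int(e), mask)
        if len(vox):
            elem_of_pair.append(np.full(len(vox), e, dtype=np.int64))
            vox_of_pair.append(vox)
    new_parts = mesh.parts.copy()
    if not elem_of_pair:
        return mesh.with_parts(new_parts)
    epair = np.concatenate(elem_of_pair)
    vpair = np.concatenate(vox_of_pair)
    weights = _pair_weights(mesh, epair, vpair, mask)
    labels = mask.data[vpair[:, 0], vpair[:, 1], vpair[:, 2]].astype(np.int64)

    # accumulate per (element, label)
    n_labels = int(labels.max(initial=0)) + 1
    pos = {int(e): i for i, e in enumerate(elig_ids)}
    rows = np.array([pos[int(e)] for e in epair], dtype=np.int64)
    acc = np.zeros((len(elig_ids), n_labels), dtype=np.int64)
    np.add.at(acc, (rows, labels), weights)

    n_zero = 0
    for i, e in enumerate(elig_ids):
        row = acc[i]
        if not include_background:
            row = row.copy()
            row[0] = 0
        total = row.sum()
        if total == 0:
            n_zero += 1
            continue
        best = row.max()
        winners = np.flatnonzero(row == best)
        if len(winners) > 1:
            continue  # tie: keep prior part
        lab = int(winners[0])
        if lab == 0:
            continue  # background wins: keep prior part
        name = tmap.get(lab)
        if name is None:
            continue
        new_parts[e] = name
    if n_zero:
        log.info("regroup: %d eligible elements had zero total weight", n_zero)
    return mesh.with_parts(new_parts)
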