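"""Hexahedral FE mesh data model, I/O, morphing, and element quality.

Node ordering follows the standard 8-node brick convention (VTK/Abaqus
C3D8): nodes 0-3 are the bottom face counter-clockwise seen from outside
(i.e. from below -z looking up the element is right-handed), nodes 4-7 the
top face above them.

Quality metrics follow common preprocessor conventions and are documented
in detail in docs/methods.md; note that "Jacobian" here is the
corner-normalized *scaled Jacobian* (1 for a perfect cube, <= 0 for a
degenerate or inverted element) — distinct from the image-space Jacobian
map det(I + grad u) of a displacement field.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dispfield import DisplacementField, sample_field


class MeshFormatError(ValueError):
    pass


# corner -> the three neighbour corners whose emanating edges form a
# right-handed frame on a reference cube
_CORNER_TRIPLES = (
    (1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
    (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3),
)

# the six quad faces, cyclically ordered
_FACES = (
    (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
    (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7),
)

# edges grouped by local axis (for the aspect ratio)
_AXIS_EDGES = (
    ((0, 1), (3, 2), (4, 5), (7, 6)),
    ((0, 3), (1, 2), (4, 7), (5, 6)),
    ((0, 4), (1, 5), (2, 6), (3, 7)),
)

#: Default pass thresholds: (metric, bound, kind) where kind says whether an
#: element passes when its value is >= or <= the bound.
DEFAULT_THRESHOLDS: dict[str, tuple[float, str]] = {
    "scaled_jacobian": (0.5, "ge"),
    "warpage": (30.0, "le"),
    "skew": (60.0, "le"),
    "aspect_ratio": (8.0, "le"),
    "min_angle": (30.0, "ge"),
    "max_angle": (150.0, "le"),
}


@dataclass
class HexMesh:
    """Nodes, 8-node hex elements and per-element part labels."""

    nodes: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elems, 8) node indices
    parts: np.ndarray  # (n_elems,) part names (str)
    quads: np.ndarray | None = None  # (n_quads, 4) optional shell elements
    quad_parts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.parts = np.asarray(self.parts, dtype=object)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshFormatError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise MeshFormatError("elements must be (m, 8)")
        if len(self.parts) != len(self.elements):
            raise MeshFormatError("one part label per element required")
        if self.elements.size:
            if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
                raise MeshFormatError("element references a missing node")
            uniq = np.sort(self.elements, axis=1)
            if np.any(uniq[:, 1:] == uniq[:, :-1]):
                raise MeshFormatError("hex element with repeated node ids")
        if self.quads is not None:
            self.quads = np.asarray(self.quads, dtype=np.int64)
            if self.quad_parts is None:
                self.quad_parts = np.asarray(
                    ["shell"] * len(self.quads), dtype=object
                )

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_corners(self, elem: int | np.ndarray | None = None) -> np.ndarray:
        """Corner coordinates, shape (..., 8, 3)."""
        conn = self.elements if elem is None else np.atleast_2d(self.elements[elem])
        return self.nodes[conn]

    def part_names(self) -> list[str]:
        return sorted(set(self.parts.tolist()))

    def with_parts(self, parts: np.ndarray) -> "HexMesh":
        return replace(self, parts=np.asarray(parts, dtype=object))


def morph_mesh(mesh: HexMesh, f: DisplacementField) -> HexMesh:
    """Move every node by the interpolated displacement: x_i = X_i + u_i.

    Connectivity and part labels are untouched; nodes outside the field's
    grid get zero displacement.
    """
    u = sample_field(f, mesh.nodes)
    return replace(mesh, nodes=mesh.nodes + u)


# --------------------------------------------------------------------------
# quality metrics (vectorised over elements; corners has shape (m, 8, 3))

def _corner_jacobians(corners: np.ndarray) -> np.ndarray:
    """Normalized corner determinants, shape (m, 8)."""
    m = corners.shape[0]
    dets = np.empty((m, 8))
    for c, (a, b, d) in enumerate(_CORNER_TRIPLES):
        e1 = corners[:, a] - corners[:, c]
        e2 = corners[:, b] - corners[:, c]
        e3 = corners[:, d] - corners[:, c]
        n1 = np.linalg.norm(e1, axis=1)
        n2 = np.linalg.norm(e2, axis=1)
        n3 = np.linalg.norm(e3, axis=1)
        denom = n1 * n2 * n3
        det = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0, det / np.where(denom > 0, denom, 1.0), -1.0)
        dets[:, c] = out
    return dets


def scaled_jacobian(mesh: HexMesh, elem: int | None = None) -> np.ndarray | float:
    """Minimum normalized corner Jacobian per element.

    1.0 for a perfect cube (any uniform scaling leaves it unchanged),
    <= 0 for degenerate or inverted elements.
    """
    corners = mesh.element_corners(elem)
    vals = _corner_jacobians(corners).min(axis=1)
    return float(vals[0]) if elem is not None and np.isscalar(elem) else vals


def _face_points(corners: np.ndarray) -> np.ndarray:
    """(m, 6, 4, 3) corner coordinates per face."""
    return np.stack([corners[:, list(face)] for face in _FACES], axis=1)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.einsum("...i,...i->...", u, v) / np.where(nu * nv > 0, nu * nv, 1.0)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def warpage(mesh: HexMesh) -> np.ndarray:
    """Max over faces of the angle (deg) between corner-triangle normals.

    For each quad face and each of its two diagonal splits, the angle
    between the two triangle normals; planar faces score 0.
    """
    fp = _face_points(mesh.element_corners())  # (m, 6, 4, 3)
    p0, p1, p2, p3 = (fp[..., i, :] for i in range(4))
    angles = []
    for tri_a, tri_b in ((((p0, p1, p2), (p0, p2, p3))), ((p1, p2, p3), (p1, p3, p0))):
        na = np.cross(tri_a[1] - tri_a[0], tri_a[2] - tri_a[0])
        nb = np.cross(tri_b[1] - tri_b[0], tri_b[2] - tri_b[0])
        angles.append(_angle_deg(na, nb))
    return np.maximum(*angles).max(axis=1)


def skew(mesh: HexMesh) -> np.ndarray:
    """Max over faces of |90 deg - angle between the face mid-lines|."""
    fp = _face_points(mesh.element_corners())
    m1 = (fp[..., 1, :] + fp[..., 2, :]) / 2 - (fp[..., 0, :] + fp[..., 3, :]) / 2
    m2 = (fp[..., 2, :] + fp[..., 3, :]) / 2 - (fp[..., 0, :] + fp[..., 1, :]) / 2
    ang = _angle_deg(m1, m2)
    return np.abs(90.0 - ang).max(axis=1)


def aspect_ratio(mesh: HexMesh) -> np.ndarray:
    """Max/min of the mean edge length along the three local axes."""
    corners = mesh.element_corners()
    means = []
    for axis_edges in _AXIS_EDGES:
        lens = [
            np.linalg.norm(corners[:, b] - corners[:, a], axis=1)
            for a, b in axis_edges
        ]
        means.append(np.mean(lens, axis=0))
    means_arr = np.stack(means, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return means_arr.max(axis=1) / np.where(
            means_arr.min(axis=1) > 0, means_arr.min(axis=1), np.nan
        )


def face_angles(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    """(min, max) interior quad-face angle (deg) per element."""
    fp = _face_points(mesh.element_corners())  # (m, 6, 4, 3)
    angs = []
    for i in range(4):
        p = fp[..., i, :]
        prev = fp[..., (i - 1) % 4, :]
        nxt = fp[..., (i + 1) % 4, :]
        angs.append(_angle_deg(prev - p, nxt - p))
    a = np.stack(angs, axis=-1)  # (m, 6, 4)
    return a.min(axis=(1, 2)), a.max(axis=(1, 2))


@dataclass
class ElementQualityReport:
    """Pass percentages and extrema for the six hex quality metrics."""

    n_elements: int
    percentages: dict[str, float]  # metric -> % of elements passing
    extrema: dict[str, float]  # metric -> min or max, whichever binds
    worst_elements: dict[str, int] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def satisfactory(self) -> bool:
        """At least 95% of elements with scaled Jacobian >= 0.5."""
        return self.percentages["scaled_jacobian"] >= 95.0

    def to_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "percentages": self.percentages,
            "extrema": self.extrema,
            "worst_elements": self.worst_elements,
        }


def quality_report(
    mesh: HexMesh,
    thresholds: dict[str, tuple[float, str]] | None = None,
) -> ElementQualityReport:
    """All six quality metrics aggregated over the mesh's hex elements."""
    if mesh.n_elements == 0:
        raise ValueError("cannot assess quality of an empty mesh")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    amin, amax = face_angles(mesh)
    vals = {
        "scaled_jacobian": np.asarray(scaled_jacobian(mesh)),
        "warpage": warpage(mesh),
        "skew": skew(mesh),
        "aspect_ratio": aspect_ratio(mesh),
        "min_angle": amin,
        "max_angle": amax,
    }
    pct: dict[str, float] = {}
    ext: dict[str, float] = {}
    worst: dict[str, int] = {}
    for name, v in vals.items():
        bound, kind = thr[name]
        ok = v >= bound if kind == "ge" else v <= bound
        pct[name] = 100.0 * float(np.count_nonzero(ok)) / len(v)
        if kind == "ge":
            ext[name] = float(np.nanmin(v))
            worst[name] = int(np.nanargmin(v))
        else:
            ext[name] = float(np.nanmax(v))
            worst[name] = int(np.nanargmax(v))
    return ElementQualityReport(
        n_elements=mesh.n_elements,
        percentages=pct,
        extrema=ext,
        worst_elements=worst,
        values=vals,
    )


# --------------------------------------------------------------------------
# I/O: VTK legacy ASCII, VTK XML (.vtu) ASCII, minimal Abaqus .inp

def _part_table(parts: np.ndarray) -> tuple[np.ndarray, dict[int, str]]:
    names = sorted(set(parts.tolist()))
    name_to_id = {n: i + 1 for i, n in enumerate(names)}
    ids = np.array([name_to_id[p] for p in parts], dtype=np.int64)
    return ids, {i: n for n, i in name_to_id.items()}


def write_mesh(mesh: HexMesh, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = {".vtk": "vtk", ".vtu": "vtu", ".inp": "abaqus"}.get(
            path.suffix.lower(), "vtk"
        )
    if dialect == "vtk":
        _write_vtk_legacy(mesh, path)
    elif dialect == "vtu":
        _write_vtu(mesh, path)
    elif dialect == "abaqus":
        _write_abaqus(mesh, path)
    else:
        raise MeshFormatError(f"unknown mesh dialect {dialect!r}")


def read_mesh(path: str | Path, dialect: str | None = None) -> HexMesh:
    path = Path(path)
    if dialect is None:
        dialect = {".vtk": "vtk", ".vtu": "vtu", ".inp": "abaqus"}.get(
            path.suffix.lower(), "vtk"
        )
    if dialect == "vtk":
        return _read_vtk_legacy(path)
    if dialect == "vtu":
        return _read_vtu(path)
    if dialect == "abaqus":
        return _read_abaqus(path)
    raise MeshFormatError(f"unknown mesh dialect {dialect!r}")


def _write_vtk_legacy(mesh: HexMesh, path: Path) -> None:
    ids, table = _part_table(mesh.parts)
    qids = None
    if mesh.quads is not None and len(mesh.quads):
        qp = np.asarray(mesh.quad_parts, dtype=object)
        all_ids, table = _part_table(
            np.concatenate([mesh.parts, qp])
        )
        ids, qids = all_ids[: len(mesh.parts)], all_ids[len(mesh.parts):]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"headmorph parts={json.dumps(table)}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        nq = 0 if mesh.quads is None else len(mesh.quads)
        ncells = mesh.n_elements + nq
        fh.write(f"CELLS {ncells} {9 * mesh.n_elements + 5 * nq}\n")
        for e in mesh.elements:
            fh.write("8 " + " ".join(map(str, e)) + "\n")
        if mesh.quads is not None:
            for q in mesh.quads:
                fh.write("4 " + " ".join(map(str, q)) + "\n")
        fh.write(f"CELL_TYPES {ncells}\n")
        fh.write("".join("12\n" for _ in range(mesh.n_elements)))
        fh.write("".join("9\n" for _ in range(nq)))
        fh.write(f"CELL_DATA {ncells}\nSCALARS part int 1\nLOOKUP_TABLE default\n")
        for i in ids:
            fh.write(f"{i}\n")
        if qids is not None:
            for i in qids:
                fh.write(f"{i}\n")


def _read_vtk_legacy(path: Path) -> HexMesh:
    tokens_lines = Path(path).read_text().splitlines()
    if len(tokens_lines) < 4 or not tokens_lines[0].startswith("# vtk"):
        raise MeshFormatError(f"{path}: not a VTK legacy file")
    table: dict[int, str] = {}
    if "parts=" in tokens_lines[1]:
        try:
            raw = json.loads(tokens_lines[1].split("parts=", 1)[1])
            table = {int(k): v for k, v in raw.items()}
        except (json.JSONDecodeError, ValueError):
            table = {}
    if "ASCII" not in tokens_lines[2].upper():
        raise MeshFormatError(f"{path}: only ASCII VTK files are supported")
    toks = " ".join(tokens_lines[4:]).split()
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        while pos < len(toks) and toks[pos].upper() != word:
            pos += 1
        if pos >= len(toks):
            raise MeshFormatError(f"{path}: missing {word} section")
        pos += 1

    expect("POINTS")
    npts = int(toks[pos]); pos += 2  # skip dtype
    nodes = np.array(toks[pos: pos + 3 * npts], dtype=float).reshape(npts, 3)
    pos += 3 * npts
    expect("CELLS")
    ncells = int(toks[pos]); nints = int(toks[pos + 1]); pos += 2
    cell_toks = np.array(toks[pos: pos + nints], dtype=np.int64)
    pos += nints
    cells = []
    cp = 0
    for _ in range(ncells):
        n = int(cell_toks[cp])
        cells.append(cell_toks[cp + 1: cp + 1 + n])
        cp += 1 + n
    expect("CELL_TYPES")
    nct = int(toks[pos]); pos += 1
    ctypes = np.array(toks[pos: pos + nct], dtype=int)
    pos += nct
    part_ids = np.zeros(ncells, dtype=np.int64)
    rest = " ".join(toks[pos:])
    if "CELL_DATA" in rest.upper():
        expect("CELL_DATA")
        pos += 1
        expect("LOOKUP_TABLE")
        pos += 1
        part_ids = np.array(toks[pos: pos + ncells], dtype=np.int64)
    hexes, hparts, quads, qparts = [], [], [], []
    for cell, ctype, pid in zip(cells, ctypes, part_ids):
        name = table.get(int(pid), str(pid))
        if ctype == 12:
            hexes.append(cell)
            hparts.append(name)
        elif ctype == 9:
            quads.append(cell)
            qparts.append(name)
        else:
            raise MeshFormatError(
                f"{path}: unsupported VTK cell type {ctype} (only hexahedron"
                " 12 and quad 9 are handled)"
            )
    return HexMesh(
        nodes=nodes,
        elements=np.array(hexes, dtype=np.int64).reshape(-1, 8),
        parts=np.array(hparts, dtype=object),
        quads=np.array(quads, dtype=np.int64).reshape(-1, 4) if quads else None,
        quad_parts=np.array(qparts, dtype=object) if quads else None,
    )


def _write_vtu(mesh: HexMesh, path: Path) -> None:
    ids, table = _part_table(mesh.parts)
    n, m = len(mesh.nodes), mesh.n_elements
    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    root.append(ET.Comment(f"headmorph parts={json.dumps(table)}"))
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n), NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = " ".join(f"{v:.10g}" for v in mesh.nodes.ravel())
    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(
        cells, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = " ".join(map(str, mesh.elements.ravel()))
    offs = ET.SubElement(
        cells, "DataArray", type="Int64", Name="offsets", format="ascii"
    )
    offs.text = " ".join(str(8 * (i + 1)) for i in range(m))
    types = ET.SubElement(
        cells, "DataArray", type="UInt8", Name="types", format="ascii"
    )
    types.text = " ".join("12" for _ in range(m))
    cdata = ET.SubElement(piece, "CellData")
    pa = ET.SubElement(
        cdata, "DataArray", type="Int64", Name="part", format="ascii"
    )
    pa.text = " ".join(map(str, ids))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_vtu(path: Path) -> HexMesh:
    text = Path(path).read_text()
    tree = ET.fromstring(text)
    table: dict[int, str] = {}
    if "parts=" in text:
        try:
            raw = json.loads(text.split("parts=", 1)[1].split("-->", 1)[0])
            table = {int(k): v for k, v in raw.items()}
        except (json.JSONDecodeError, ValueError):
            table = {}
    ns = ""
    piece = tree.find(f".//{ns}Piece")
    if piece is None:
        raise MeshFormatError(f"{path}: no UnstructuredGrid Piece found")

    def arr(xpath_name: str, parent: str) -> np.ndarray:
        for da in piece.iter("DataArray"):
            if da.get("Name") == xpath_name or (
                xpath_name == "points" and da.get("NumberOfComponents") == "3"
                and parent == "Points"
            ):
                return np.array((da.text or "").split(), dtype=float)
        raise MeshFormatError(f"{path}: missing DataArray {xpath_name}")

    nodes = arr("points", "Points").reshape(-1, 3)
    conn = arr("connectivity", "Cells").astype(np.int64)
    offsets = arr("offsets", "Cells").astype(np.int64)
    ctypes = arr("types", "Cells").astype(int)
    if not np.all(ctypes == 12):
        bad = int(ctypes[ctypes != 12][0])
        raise MeshFormatError(f"{path}: unsupported VTK cell type {bad}")
    if not np.all(np.diff(np.concatenate([[0], offsets])) == 8):
        raise MeshFormatError(f"{path}: non-hex connectivity offsets")
    elements = conn.reshape(-1, 8)
    try:
        pids = arr("part", "CellData").astype(np.int64)
    except MeshFormatError:
        pids = np.zeros(len(elements), dtype=np.int64)
    parts = np.array([table.get(int(i), str(i)) for i in pids], dtype=object)
    return HexMesh(nodes=nodes, elements=elements, parts=parts)


def _write_abaqus(mesh: HexMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("*HEADING\nheadmorph export\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {p[0]:.10g}, {p[1]:.10g}, {p[2]:.10g}\n")
        eid = 1
        for part in sorted(set(mesh.parts.tolist())):
            fh.write(f"*ELEMENT, TYPE=C3D8, ELSET={part}\n")
            for e in mesh.elements[mesh.parts == part]:
                fh.write(f"{eid}, " + ", ".join(str(n + 1) for n in e) + "\n")
                eid += 1
        if mesh.quads is not None and len(mesh.quads):
            for part in sorted(set(np.asarray(mesh.quad_parts).tolist())):
                fh.write(f"*ELEMENT, TYPE=S4, ELSET={part}\n")
                sel = np.asarray(mesh.quad_parts, dtype=object) == part
                for q in mesh.quads[sel]:
                    fh.write(f"{eid}, " + ", ".join(str(n + 1) for n in q) + "\n")
                    eid += 1


def _read_abaqus(path: Path) -> HexMesh:
    node_ids: list[int] = []
    coords: list[list[float]] = []
    hexes: list[list[int]] = []
    hparts: list[str] = []
    quads: list[list[int]] = []
    qparts: list[str] = []
    mode = None
    elset = ""
    eltype = ""
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            key = line.split(",")[0].strip().upper()
            opts = {
                kv.split("=")[0].strip().upper(): kv.split("=")[1].strip()
                for kv in line.split(",")[1:]
                if "=" in kv
            }
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                eltype = opts.get("TYPE", "").upper()
                elset = opts.get("ELSET", "solid")
                if eltype.startswith("C3D8"):
                    mode = "hex"
                elif eltype.startswith("S4"):
                    mode = "quad"
                else:
                    raise MeshFormatError(
                        f"{path}: unsupported Abaqus element type {eltype}"
                    )
            else:
                mode = None
            continue
        vals = [v.strip() for v in line.split(",") if v.strip()]
        if mode == "node":
            node_ids.append(int(vals[0]))
            coords.append([float(v) for v in vals[1:4]])
        elif mode == "hex":
            hexes.append([int(v) for v in vals[1:9]])
            hparts.append(elset)
        elif mode == "quad":
            quads.append([int(v) for v in vals[1:5]])
            qparts.append(elset)
    if not node_ids:
        raise MeshFormatError(f"{path}: no *NODE section found")
    id_map = {nid: i for i, nid in enumerate(node_ids)}
    remap = np.vectorize(id_map.__getitem__)
    return HexMesh(
        nodes=np.asarray(coords, dtype=float),
        elements=remap(np.asarray(hexes, dtype=np.int64)).reshape(-1, 8),
        parts=np.array(hparts, dtype=object),
        quads=remap(np.asarray(quads, dtype=np.int64)).reshape(-1, 4)
        if quads
        else None,
        quad_parts=np.array(qparts, dtype=object) if quads else None,
    )
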