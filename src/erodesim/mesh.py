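"""Tetrahedral volume meshes: containers, Gmsh MSH I/O, structured cylinder
generation, and the face-adjacency primitives the erosion engine builds on.

A mesh is stored as flat numpy arrays (node coordinates, 4-column element
connectivity, per-element volumes).  Node and element ids are contiguous
1-based integers internally, independent of the numbering found in a file;
iteration order is therefore deterministic, which the erosion engine relies
on for reproducible random-number consumption.

Faces are identified by the sorted triple of their node ids.  In a valid
tetrahedral mesh a face is shared by at most two elements: interior faces by
exactly two, boundary faces by exactly one.  An element's *exposed-face
count* is the number of its four faces not shared with another active
element, i.e. the number of faces in contact with the surrounding medium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MeshError",
    "DegenerateElementError",
    "TetMesh",
    "tet_volume",
    "generate_cylinder_mesh",
    "load_mesh",
    "write_mesh",
    "compute_exposure",
    "boundary_mask",
]

#: element volume below which a tetrahedron is considered degenerate (mm^3)
DEGENERATE_VOLUME = 1e-12

# local node indices of the four triangular faces of a tetrahedron
_FACE_CORNERS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


class MeshError(ValueError):
    """Raised for invalid mesh files or mesh construction parameters."""


class DegenerateElementError(MeshError):
    """Raised when a tetrahedron has (numerically) zero volume."""


def tet_volume(p0, p1, p2, p3) -> float:
    """Volume of the tetrahedron spanned by four 3D points, in mm^3.

    The result is |det([p1-p0, p2-p0, p3-p0])| / 6 and is therefore
    invariant under any permutation of the four vertices.

    Raises
    ------
    DegenerateElementError
        If the four points are (numerically) coplanar.
    """
    p0 = np.asarray(p0, dtype=float)
    mat = np.stack([np.asarray(p, dtype=float) - p0 for p in (p1, p2, p3)])
    vol = abs(float(np.linalg.det(mat))) / 6.0
    if vol < DEGENERATE_VOLUME:
        raise DegenerateElementError(
            f"degenerate (coplanar) tetrahedron, volume {vol:g} mm^3"
        )
    return vol


def _tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Vectorised unsigned volumes of ``elements`` (0-based rows into ``nodes``)."""
    p = nodes[elements]  # (E, 4, 3)
    d = p[:, 1:] - p[:, :1]  # (E, 3, 3)
    det = (
        d[:, 0, 0] * (d[:, 1, 1] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 1])
        - d[:, 0, 1] * (d[:, 1, 0] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 0])
        + d[:, 0, 2] * (d[:, 1, 0] * d[:, 2, 1] - d[:, 1, 1] * d[:, 2, 0])
    )
    return np.abs(det) / 6.0


@dataclass
class TetMesh:
    """An all-tetrahedral volume mesh with per-element volumes.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm.  Row ``k`` is node id ``k + 1``.
    elements : (E, 4) int array
        0-based node row indices of each tetrahedron.  Row ``k`` is element
        id ``k + 1``.
    volumes : (E,) float array
        Element volumes in mm^3, all strictly positive.
    source_node_ids, source_element_ids : (N,), (E,) int arrays
        The ids carried by the file the mesh was loaded from (or the
        internal ids for generated meshes); kept so round-trips are stable.
    """

    nodes: np.ndarray
    elements: np.ndarray
    volumes: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_element_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise MeshError("elements must be an (E, 4) array")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshError("element refers to a node that does not exist")
        if self.volumes is None:
            self.volumes = _tet_volumes(self.nodes, self.elements)
        bad = np.flatnonzero(self.volumes < DEGENERATE_VOLUME)
        if bad.size:
            raise DegenerateElementError(
                f"degenerate tetrahedra (volume < {DEGENERATE_VOLUME:g} mm^3) "
                f"at element ids {[int(b) + 1 for b in bad[:10]]}"
            )
        if self.source_node_ids is None:
            self.source_node_ids = np.arange(1, len(self.nodes) + 1, dtype=np.int64)
        if self.source_element_ids is None:
            self.source_element_ids = np.arange(
                1, len(self.elements) + 1, dtype=np.int64
            )

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def total_volume(self) -> float:
        """Sum of all element volumes (mm^3), the undegraded part volume."""
        return float(self.volumes.sum())

    def element_volume(self, element_id: int) -> float:
        """Volume (mm^3) of the element with 1-based id ``element_id``."""
        return float(self.volumes[element_id - 1])

    def node_coords(self, node_id: int) -> np.ndarray:
        """Coordinates (mm) of the node with 1-based id ``node_id``."""
        return self.nodes[node_id - 1]

    def full_active(self) -> np.ndarray:
        """Boolean mask with every element active."""
        return np.ones(self.n_elements, dtype=bool)

    def submesh(self, active: np.ndarray) -> "TetMesh":
        """New TetMesh containing only the ``active`` elements and the nodes
        they reference, renumbered contiguously (ascending original id)."""
        active = _as_mask(active, self.n_elements)
        elems = self.elements[active]
        used = np.unique(elems)
        remap = np.full(self.n_nodes, -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        return TetMesh(
            nodes=self.nodes[used],
            elements=remap[elems],
            volumes=self.volumes[active],
        )


def _as_mask(active, n_elements: int) -> np.ndarray:
    """Normalise an active-element spec (bool mask or iterable of 1-based ids)."""
    active = np.asarray(active)
    if active.dtype == bool:
        if active.shape != (n_elements,):
            raise MeshError("active mask length does not match element count")
        return active
    mask = np.zeros(n_elements, dtype=bool)
    mask[active.astype(np.int64) - 1] = True
    return mask


# ---------------------------------------------------------------------------
# Face adjacency / exposure
# ---------------------------------------------------------------------------


def _face_keys(elements: np.ndarray, n_nodes: int) -> np.ndarray:
    """Encode the 4 faces of each element as sortable int64 keys, shape (E, 4).

    A face key is the sorted node triple (a < b < c) packed positionally; two
    elements share a face iff they produce the same key.
    """
    faces = elements[:, _FACE_CORNERS]  # (E, 4, 3)
    faces = np.sort(faces, axis=2)
    base = np.int64(n_nodes)
    if base ** 3 >= np.iinfo(np.int64).max // 2:  # pragma: no cover - huge meshes
        raise MeshError("mesh too large for packed face keys")
    return (faces[..., 0] * base + faces[..., 1]) * base + faces[..., 2]


def compute_exposure(mesh: TetMesh, active) -> np.ndarray:
    """Exposed-face count for every element, computed over the active set.

    Returns an (E,) int8 array: for an active element, the number of its
    four faces (0..4) not shared with another *active* element — i.e. the
    faces in direct contact with the degradation medium; inactive elements
    get 0.  Elements with count >= 1 are the boundary elements.
    """
    active = _as_mask(active, mesh.n_elements)
    idx = np.flatnonzero(active)
    out = np.zeros(mesh.n_elements, dtype=np.int8)
    if idx.size == 0:
        return out
    keys = _face_keys(mesh.elements[idx], mesh.n_nodes)
    flat = keys.ravel()
    _, inv, cnt = np.unique(flat, return_inverse=True, return_counts=True)
    exposed = (cnt[inv] == 1).reshape(idx.size, 4)
    out[idx] = exposed.sum(axis=1, dtype=np.int8)
    return out


def boundary_mask(mesh: TetMesh, active) -> np.ndarray:
    """Boolean mask of active elements with at least one exposed face."""
    return compute_exposure(mesh, active) >= 1


def face_ownership_counts(mesh: TetMesh) -> np.ndarray:
    """Number of owning elements per distinct face of the full mesh.

    For a watertight (manifold) tetrahedral mesh every entry is 1 (boundary
    face) or 2 (interior face).
    """
    keys = _face_keys(mesh.elements, mesh.n_nodes)
    _, cnt = np.unique(keys.ravel(), return_counts=True)
    return cnt


# ---------------------------------------------------------------------------
# Structured cylinder generator
# ---------------------------------------------------------------------------

def _square_to_disk(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concentric map of the square [-1,1]^2 onto the unit disk.

    Square rings max(|u|,|v|) = m map onto circles of radius m, so a uniform
    grid yields concentric rings of near-uniform cells (a structured grid in
    the sense of a mapped mesh, not a polar fan with tiny slivers at the
    axis).
    """
    m = np.maximum(np.abs(u), np.abs(v))
    r = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, m / np.where(r > 0, r, 1.0), 0.0)
    return u * scale, v * scale


def generate_cylinder_mesh(
    diameter: float,
    length: float,
    radial_divisions: int = 8,
    axial_divisions: int = 40,
) -> TetMesh:
    """Structured all-tetrahedral mesh of a solid cylinder (filament).

    The cross-section is a (2*radial_divisions)^2 square grid mapped
    concentrically onto the disk.  Each quad cell is split along whichever
    diagonal balances the two triangle areas best (this keeps element
    volumes near-uniform despite the shear the map introduces near its
    diagonals); each triangle is extruded through ``axial_divisions``
    uniform layers and every triangular prism is cut into 3 tetrahedra with
    the sorted-vertex rule, which makes the split conforming across shared
    faces.  Element count is ``24 * radial_divisions**2 * axial_divisions``.

    The outer surface is the inscribed polygon with ``8*radial_divisions``
    sides, so the meshed volume approaches pi*(d/2)^2*L from below as the
    cross-section is refined (relative deficit ~ 2*pi^2/(3*(8*nr)^2)).

    Parameters
    ----------
    diameter, length : float
        Cylinder diameter and length in mm (the degradation experiments used
        a 1.9 mm x 50.3 mm extruded filament).
    radial_divisions : int
        Cells along a radius of the cross-section (>= 1).
    axial_divisions : int
        Cell layers along the axis (>= 1).
    """
    if diameter <= 0 or length <= 0:
        raise MeshError("diameter and length must be positive")
    if radial_divisions < 1 or axial_divisions < 1:
        raise MeshError("radial_divisions and axial_divisions must be >= 1")

    n = 2 * radial_divisions
    radius = diameter / 2.0
    u = np.linspace(-1.0, 1.0, n + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    x2d, y2d = _square_to_disk(uu, vv)
    x2d *= radius
    y2d *= radius
    z = np.linspace(0.0, length, axial_divisions + 1)

    npl = (n + 1) * (n + 1)  # nodes per layer
    nodes = np.empty(((axial_divisions + 1) * npl, 3), dtype=float)
    flat_x = x2d.ravel()
    flat_y = y2d.ravel()
    for k in range(axial_divisions + 1):
        sl = slice(k * npl, (k + 1) * npl)
        nodes[sl, 0] = flat_x
        nodes[sl, 1] = flat_y
        nodes[sl, 2] = z[k]

    # 2D triangulation: per quad, the diagonal that balances triangle areas
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()

    def nid2(i, j):
        return i * (n + 1) + j

    ll, lr = nid2(ii, jj), nid2(ii + 1, jj)
    ur, ul = nid2(ii + 1, jj + 1), nid2(ii, jj + 1)

    def tri_areas(a, b, c):
        ax, ay = flat_x[a], flat_y[a]
        bx, by = flat_x[b], flat_y[b]
        cx, cy = flat_x[c], flat_y[c]
        return 0.5 * np.abs((bx - ax) * (cy - ay) - (by - ay) * (cx - ax))

    # diagonal ll-ur vs lr-ul; keep the split with the larger smaller-triangle
    split0 = np.stack(
        [np.stack([ll, lr, ur], axis=1), np.stack([ll, ur, ul], axis=1)], axis=1
    )  # (C, 2, 3)
    split1 = np.stack(
        [np.stack([lr, ur, ul], axis=1), np.stack([lr, ul, ll], axis=1)], axis=1
    )
    min0 = np.minimum(tri_areas(ll, lr, ur), tri_areas(ll, ur, ul))
    min1 = np.minimum(tri_areas(lr, ur, ul), tri_areas(lr, ul, ll))
    use0 = (min0 >= min1)[:, None, None]
    tris = np.where(use0, split0, split1).reshape(-1, 3)  # (2C, 3)
    tris = np.sort(tris, axis=1)  # a < b < c: sorted-vertex prism rule

    # extrude: each triangle x layer becomes a prism cut into 3 tets
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    prism_tets = np.stack(
        [
            np.stack([a, b, c, c + npl], axis=1),
            np.stack([a, b, c + npl, b + npl], axis=1),
            np.stack([a, b + npl, c + npl, a + npl], axis=1),
        ],
        axis=1,
    )  # (2C, 3, 4)
    layers = [prism_tets + k * npl for k in range(axial_divisions)]
    elements = np.concatenate(layers, axis=0).reshape(-1, 4)
    return TetMesh(nodes=nodes, elements=elements)


# ---------------------------------------------------------------------------
# MSH / VTK I/O
# ---------------------------------------------------------------------------

_SUPPORTED_READ = "ASCII MSH v2.2 and v4.1"


def load_mesh(path) -> TetMesh:
    """Load a tetrahedral mesh from a Gmsh MSH file (ASCII v2.2 or v4.1).

    Only 4-node tetrahedral volume elements (Gmsh element type 4) are kept;
    surface triangles, lines and points are ignored (a count is logged).

    Raises
    ------
    MeshError
        On unsupported MSH versions/binary files, or if the file contains no
        tetrahedra.
    DegenerateElementError
        If any tetrahedron has (numerically) zero volume.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = _split_sections(lines, path)
    fmt = sections.get("MeshFormat")
    if not fmt:
        raise MeshError(f"{path}: missing $MeshFormat section")
    version, file_type = fmt[0].split()[0], fmt[0].split()[1]
    if file_type != "0":
        raise MeshError(
            f"{path}: binary MSH not supported (supported: {_SUPPORTED_READ})"
        )
    if version.startswith("2."):
        node_ids, coords, elem_ids, conn, skipped = _parse_msh2(sections, path)
    elif version == "4.1":
        node_ids, coords, elem_ids, conn, skipped = _parse_msh41(sections, path)
    else:
        raise MeshError(
            f"{path}: unsupported MSH version {version} "
            f"(supported: {_SUPPORTED_READ})"
        )
    if skipped:
        logger.info("%s: ignored %d non-tetrahedral elements", path, skipped)
    if len(conn) == 0:
        raise MeshError(f"{path}: no tetrahedral volume elements found")

    node_ids = np.asarray(node_ids, dtype=np.int64)
    order = np.argsort(node_ids, kind="stable")
    node_ids = node_ids[order]
    coords = np.asarray(coords, dtype=float)[order]
    id_to_row = {int(t): r for r, t in enumerate(node_ids)}

    elem_ids = np.asarray(elem_ids, dtype=np.int64)
    eorder = np.argsort(elem_ids, kind="stable")
    elem_ids = elem_ids[eorder]
    conn = np.asarray(conn, dtype=np.int64)[eorder]
    try:
        rows = np.vectorize(id_to_row.__getitem__, otypes=[np.int64])(conn)
    except KeyError as exc:
        raise MeshError(f"{path}: element references unknown node {exc}") from None
    return TetMesh(
        nodes=coords,
        elements=rows,
        source_node_ids=node_ids,
        source_element_ids=elem_ids,
    )


def _split_sections(lines: list[str], path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    name = None
    buf: list[str] = []
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("$End"):
            if name is None:
                raise MeshError(f"{path}: stray {s}")
            sections[name] = buf
            name, buf = None, []
        elif s.startswith("$"):
            name = s[1:]
            buf = []
        elif name is not None:
            buf.append(s)
    if name is not None:
        raise MeshError(f"{path}: unterminated section ${name}")
    return sections


def _parse_msh2(sections, path):
    nodes = sections.get("Nodes")
    elems = sections.get("Elements")
    if nodes is None or elems is None:
        raise MeshError(f"{path}: missing $Nodes or $Elements section")
    n = int(nodes[0])
    node_ids, coords = [], []
    for ln in nodes[1 : 1 + n]:
        parts = ln.split()
        node_ids.append(int(parts[0]))
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    e = int(elems[0])
    elem_ids, conn = [], []
    skipped = 0
    for ln in elems[1 : 1 + e]:
        parts = ln.split()
        etype = int(parts[1])
        if etype != 4:
            skipped += 1
            continue
        ntags = int(parts[2])
        elem_ids.append(int(parts[0]))
        conn.append([int(t) for t in parts[3 + ntags : 7 + ntags]])
    return node_ids, coords, elem_ids, conn, skipped


def _parse_msh41(sections, path):
    nodes = sections.get("Nodes")
    elems = sections.get("Elements")
    if nodes is None or elems is None:
        raise MeshError(f"{path}: missing $Nodes or $Elements section")
    # nodes: header then per-entity blocks of tags followed by coordinates
    n_blocks = int(nodes[0].split()[0])
    node_ids, coords = [], []
    pos = 1
    for _ in range(n_blocks):
        nb = int(nodes[pos].split()[3])
        pos += 1
        tags = [int(nodes[pos + i]) for i in range(nb)]
        pos += nb
        for i in range(nb):
            parts = nodes[pos + i].split()
            coords.append([float(parts[0]), float(parts[1]), float(parts[2])])
        node_ids.extend(tags)
        pos += nb
    e_blocks = int(elems[0].split()[0])
    elem_ids, conn = [], []
    skipped = 0
    pos = 1
    for _ in range(e_blocks):
        hdr = elems[pos].split()
        etype, nb = int(hdr[2]), int(hdr[3])
        pos += 1
        for i in range(nb):
            parts = elems[pos + i].split()
            if etype == 4:
                elem_ids.append(int(parts[0]))
                conn.append([int(t) for t in parts[1:5]])
            else:
                skipped += 1
        pos += nb
    return node_ids, coords, elem_ids, conn, skipped


def write_mesh(path, mesh: TetMesh, active=None, fmt: str | None = None) -> None:
    """Write the active part of a mesh to an ASCII MSH v2.2 or legacy VTK file.

    Only active elements and the nodes they reference are written, with
    contiguous 1-based ids in ascending original order — the serialization
    is canonical, so write -> load -> write reproduces the file byte for
    byte.

    Parameters
    ----------
    path : path-like
        Output file; ``fmt`` defaults from the suffix (.msh or .vtk).
    active : bool mask or id iterable, optional
        Elements to keep (default: all).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".msh": "msh22", ".vtk": "vtk"}.get(path.suffix.lower())
        if fmt is None:
            raise MeshError(f"cannot infer format from suffix {path.suffix!r}")
    if active is None:
        active = mesh.full_active()
    active = _as_mask(active, mesh.n_elements)
    if not active.any():
        raise MeshError("refusing to write a mesh with no active elements")
    sub = mesh.submesh(active)
    if fmt == "msh22":
        text = _format_msh22(sub)
    elif fmt == "vtk":
        text = _format_vtk(sub)
    else:
        raise MeshError(f"unknown mesh format {fmt!r} (use 'msh22' or 'vtk')")
    path.write_text(text)


def _format_msh22(mesh: TetMesh) -> str:
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{i} {x:.16g} {y:.16g} {z:.16g}")
    out += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for i, row in enumerate(mesh.elements + 1, start=1):
        out.append(f"{i} 4 2 0 0 {row[0]} {row[1]} {row[2]} {row[3]}")
    out.append("$EndElements")
    return "\n".join(out) + "\n"


def _format_vtk(mesh: TetMesh) -> str:
    out = [
        "# vtk DataFile Version 2.0",
        "erodesim degraded geometry",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y, z in mesh.nodes:
        out.append(f"{x:.16g} {y:.16g} {z:.16g}")
    out.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    for row in mesh.elements:
        out.append(f"4 {row[0]} {row[1]} {row[2]} {row[3]}")
    out.append(f"CELL_TYPES {mesh.n_elements}")
    out.extend("10" for _ in range(mesh.n_elements))
    return "\n".join(out) + "\n"
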