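"""Tetrahedral meshes for the two-needle electroporation geometry.

A parametric mesher builds the standard configuration — two parallel needle
electrodes (1.2 mm diameter, 10 mm centre-to-centre, 10 mm exposed length)
inserted into a block of tissue — without an external CAD kernel: the x-y
cross-section (a box with two circular bores) is triangulated with Delaunay,
and the triangulation is extruded into conforming prisms that are split into
tetrahedra with the classic minimum-vertex-index rule, so neighbouring prisms
always agree on their shared quadrilateral diagonals.

Boundary triangles carry one of three tags: the exposed wall + flat tip of
each needle (``ELECTRODE_A``/``ELECTRODE_B``, Dirichlet surfaces) and
everything else (``OUTER``, zero normal current).  The insulated needle shaft
above the exposed band is part of ``OUTER``.

Generic MSH (Gmsh ASCII 2.2 and 4.1) import/export with named physical
groups, and legacy-VTK export of element fields, round out the module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "ELECTRODE_A", "ELECTRODE_B", "OUTER",
    "Mesh", "MeshError", "MeshFormatError",
    "build_two_needle_geometry", "build_plate_box",
    "read_mesh_msh", "write_mesh_msh", "write_vtk",
]

ELECTRODE_A = "electrode_a"
ELECTRODE_B = "electrode_b"
OUTER = "outer"

_TAGS = (ELECTRODE_A, ELECTRODE_B, OUTER)


class MeshError(ValueError):
    """Invalid mesh topology or geometry."""


class MeshFormatError(MeshError):
    """Unreadable or unsupported mesh file."""


# ---------------------------------------------------------------------------
# core container


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


@dataclass
class Mesh:
    """Tetrahedral mesh with tagged boundary triangles.

    ``tri_nodes`` stores every boundary triangle with outward orientation;
    ``tri_tag`` assigns exactly one tag per triangle and ``tri_owner`` the
    adjacent tetrahedron (used when sampling current densities on electrode
    surfaces).  Coordinates are metres, indices 0-based.
    """

    nodes: np.ndarray               # (N, 3) float
    tets: np.ndarray                # (M, 4) int
    tri_nodes: np.ndarray           # (K, 3) int, outward-oriented
    tri_tag: np.ndarray             # (K,) str
    tri_owner: np.ndarray           # (K,) int, adjacent tet
    element_volumes: np.ndarray = field(init=False)
    tri_areas: np.ndarray = field(init=False)
    tri_normals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.tri_nodes = np.asarray(self.tri_nodes, dtype=np.int64)
        self.tri_owner = np.asarray(self.tri_owner, dtype=np.int64)
        self.tri_tag = np.asarray(self.tri_tag)
        self.element_volumes = _tet_volumes(self.nodes, self.tets)
        e1 = self.nodes[self.tri_nodes[:, 1]] - self.nodes[self.tri_nodes[:, 0]]
        e2 = self.nodes[self.tri_nodes[:, 2]] - self.nodes[self.tri_nodes[:, 0]]
        cr = np.cross(e1, e2)
        nrm = np.linalg.norm(cr, axis=1)
        self.tri_areas = 0.5 * nrm
        with np.errstate(invalid="ignore", divide="ignore"):
            self.tri_normals = cr / np.where(nrm > 0, nrm, 1.0)[:, None]

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def tri_index(self, tag: str) -> np.ndarray:
        if tag not in _TAGS:
            raise MeshError(f"unknown surface tag {tag!r}")
        return np.nonzero(self.tri_tag == tag)[0]

    def surface_area(self, tag: str) -> float:
        return float(self.tri_areas[self.tri_index(tag)].sum())

    def surface_nodes(self, tag: str) -> np.ndarray:
        """Sorted unique node indices on a tagged surface."""
        return np.unique(self.tri_nodes[self.tri_index(tag)])

    def validate(self) -> None:
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise MeshError("tetrahedron references node out of range")
        bad = np.nonzero(self.element_volumes <= 0)[0]
        if bad.size:
            raise MeshError(f"non-positive volume in element {int(bad[0])}")
        for tag in (ELECTRODE_A, ELECTRODE_B):
            if not np.any(self.tri_tag == tag):
                raise MeshError(f"missing surface tag {tag!r}")
        referenced = np.unique(self.tets)
        orphans = np.setdiff1d(np.unique(self.tri_nodes), referenced)
        if orphans.size:
            raise MeshError(f"boundary references unused node {int(orphans[0])}")


# ---------------------------------------------------------------------------
# boundary extraction

_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _boundary_faces(nodes: np.ndarray, tets: np.ndarray):
    """Outward-oriented boundary triangles with their owner tets."""
    faces = tets[:, _FACE_LOCAL]                      # (M, 4, 3)
    flat = faces.reshape(-1, 3)
    owners = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(flat, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        raise MeshError("non-manifold face (shared by >2 tets)")
    sel = counts[inv] == 1
    tris, owner = flat[sel], owners[sel]
    # orient outward: normal must point away from the owner tet centroid
    cent_t = nodes[tets[owner]].mean(axis=1)
    cent_f = nodes[tris].mean(axis=1)
    nrm = np.cross(nodes[tris[:, 1]] - nodes[tris[:, 0]],
                   nodes[tris[:, 2]] - nodes[tris[:, 0]])
    flip = np.einsum("ij,ij->i", nrm, cent_f - cent_t) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris, owner


# ---------------------------------------------------------------------------
# prism extrusion (minimum-index split keeps neighbouring prisms conforming)

_PRISM_ROT = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 5, 4, 0, 2, 1],
    [4, 3, 5, 1, 0, 2],
    [5, 4, 3, 2, 1, 0],
])


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split (n, 6) prisms into (3n, 4) tets; conforming across shared quads."""
    pos = np.argmin(prisms, axis=1)
    idx = _PRISM_ROT[pos]
    I = np.take_along_axis(prisms, idx, axis=1)
    cond = np.minimum(I[:, 1], I[:, 5]) < np.minimum(I[:, 2], I[:, 4])
    tets_a = np.stack([I[:, [0, 1, 2, 5]], I[:, [0, 1, 5, 4]], I[:, [0, 4, 5, 3]]], axis=1)
    tets_b = np.stack([I[:, [0, 1, 2, 4]], I[:, [0, 4, 2, 5]], I[:, [0, 4, 5, 3]]], axis=1)
    tets = np.where(cond[:, None, None], tets_a, tets_b).reshape(-1, 4)
    return tets


def _extrude(points2d: np.ndarray, tri_layers: list[np.ndarray],
             z_levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extrude per-interval triangle sets through the given z levels."""
    n2 = len(points2d)
    nodes = np.column_stack([
        np.tile(points2d, (len(z_levels), 1)),
        np.repeat(z_levels, n2),
    ])
    all_prisms = []
    for k, tris in enumerate(tri_layers):
        lo, hi = k * n2, (k + 1) * n2
        all_prisms.append(np.column_stack([tris + lo, tris + hi]))
    tets = _split_prisms(np.vstack(all_prisms))
    vol = _tet_volumes(nodes, tets)
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    keep = np.abs(vol) > 1e-30
    return nodes, tets[keep]


def _compress(nodes: np.ndarray, tets: np.ndarray):
    """Drop nodes not referenced by any tetrahedron."""
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets]


# ---------------------------------------------------------------------------
# parametric geometries


def _graded_levels(start: float, stop: float, first: float, ratio: float = 1.6):
    """Levels from start to stop with geometrically growing spacing."""
    levels = [start]
    step = first
    while levels[-1] + step < stop - 1e-12:
        levels.append(levels[-1] + step)
        step *= ratio
    levels.append(stop)
    # merge a final sliver interval into its neighbour
    if len(levels) >= 3 and (levels[-1] - levels[-2]) < 0.3 * (levels[-2] - levels[-3]):
        del levels[-2]
    return np.array(levels)


def build_two_needle_geometry(
    electrodeDiameter: float = 1.2e-3,
    centreSpacing: float = 10e-3,
    exposedLength: float = 10e-3,
    domainSize: float = 60e-3,
    targetEdgeLength: float = 2.5e-3,
    resolve_near_field: bool = True,
) -> Mesh:
    """Mesh a tissue block with two parallel needle electrodes.

    The needles run along z, entering through the top face; the exposed
    conductive band spans ``exposedLength`` centred on z = 0 and ends in a
    flat tip.  ``targetEdgeLength`` controls the bulk resolution; with
    ``resolve_near_field`` (default) geometrically graded rings and z levels
    resolve the steep field around the needles and at the band edges, which
    quantitative electrode currents require.  Disabling it yields minimal
    element counts for structural or iteration-count studies.
    """
    r = electrodeDiameter / 2.0
    if centreSpacing <= electrodeDiameter:
        raise MeshError("electrode bores overlap: centreSpacing <= electrodeDiameter")
    if domainSize < 5 * centreSpacing + electrodeDiameter:
        raise MeshError("domainSize too small for margin >= 2*centreSpacing")
    if domainSize < exposedLength + 2 * centreSpacing:
        raise MeshError("domainSize too small along the needle axis")
    if targetEdgeLength <= 0:
        raise MeshError("targetEdgeLength must be positive")

    h = float(targetEdgeLength)
    half = domainSize / 2.0
    centres = np.array([[-centreSpacing / 2.0, 0.0], [centreSpacing / 2.0, 0.0]])

    # --- 2-D point cloud --------------------------------------------------
    # geometrically graded rings resolve the ~1/rho field around each needle
    if resolve_near_field:
        dr0 = r * np.clip(0.45 * h / 5e-3, 0.02, 0.60)
        n_theta = max(12, int(np.ceil(2 * np.pi * r / (1.7 * dr0))))
        radii = [r]
        while radii[-1] < 3.5 * r:
            radii.append(radii[-1] + dr0 * (radii[-1] / r) ** 1.2)
    else:
        dr0 = 0.9 * r
        n_theta = max(12, int(np.ceil(2 * np.pi * r / (0.75 * h))))
        radii = [r]
    pts = []
    for c in centres:
        for rho in radii:
            theta = np.arange(n_theta) * (2 * np.pi / n_theta)
            ring = rho * np.column_stack([np.cos(theta), np.sin(theta)])
            pts.append(c + ring)

    h_fine = min(h, max(3.0 * r, 0.55 * h))
    fx = centreSpacing / 2.0 + 3 * r + h_fine
    fy = 3 * r + h_fine
    nx = max(2, int(round(2 * fx / h_fine)))
    ny = max(2, int(round(2 * fy / h_fine)))
    gx, gy = np.meshgrid(np.linspace(-fx, fx, nx + 1), np.linspace(-fy, fy, ny + 1))
    fine = np.column_stack([gx.ravel(), gy.ravel()])
    d_min = np.min(np.linalg.norm(fine[:, None, :] - centres[None], axis=2), axis=1)
    r_clear = max(r + 0.55 * h_fine, radii[-1] + 0.45 * h_fine)
    fine = fine[d_min > r_clear]
    pts.append(fine)

    h_c = min(2.5 * h, half / 2.0)
    nc = max(4, int(round(domainSize / h_c)))
    cg = np.linspace(-half, half, nc + 1)
    cx, cy = np.meshgrid(cg, cg)
    coarse = np.column_stack([cx.ravel(), cy.ravel()])
    inside_fine = (np.abs(coarse[:, 0]) < fx + 0.4 * h_c) & (np.abs(coarse[:, 1]) < fy + 0.4 * h_c)
    pts.append(coarse[~inside_fine])

    points2d = np.vstack(pts)

    tri = Delaunay(points2d)
    simplices = tri.simplices
    cent = points2d[simplices].mean(axis=1)
    in_bore = np.zeros(len(simplices), dtype=bool)
    for c in centres:
        in_bore |= np.linalg.norm(cent - c, axis=1) < r * (1.0 - 1e-6)
    tris_full = simplices
    tris_holed = simplices[~in_bore]

    # --- z levels ---------------------------------------------------------
    z_tip, z_top = -exposedLength / 2.0, exposedLength / 2.0
    # z spacing refines toward the band ends, where the tip/insulation edges
    # concentrate the field, starting from the near-needle radial scale
    if resolve_near_field:
        s0 = 2.0 * dr0
        lower = z_tip + _graded_levels(0.0, exposedLength / 2.0, s0, 1.8)
        upper = z_top - _graded_levels(0.0, exposedLength / 2.0, s0, 1.8)
        band = np.unique(np.concatenate([lower, upper[::-1]]))
    else:
        s0 = 1.5 * h
        nz_band = max(3, int(round(exposedLength / (1.3 * h))))
        band = np.linspace(z_tip, z_top, nz_band + 1)
    below = z_tip - _graded_levels(0.0, half + z_tip, s0, 2.0)   # descending to floor
    below = below[::-1][:-1]                                     # ascending, z_tip kept by band
    above = z_top + _graded_levels(0.0, half - z_top, s0, 2.0)[1:]
    z_levels = np.concatenate([below, band, above])

    tri_layers = []
    for z0, z1 in zip(z_levels[:-1], z_levels[1:]):
        zc = 0.5 * (z0 + z1)
        tri_layers.append(tris_full if zc < z_tip else tris_holed)

    nodes, tets = _compress(*_extrude(points2d, tri_layers, z_levels))

    # --- boundary tagging -------------------------------------------------
    tris, owner = _boundary_faces(nodes, tets)
    tol_r = r * 1e-6 + 1e-12
    tol_z = 1e-9
    tag = np.full(len(tris), OUTER, dtype=object)
    xy = nodes[:, :2]
    for label, c in ((ELECTRODE_A, centres[0]), (ELECTRODE_B, centres[1])):
        on_cyl = np.linalg.norm(xy - c, axis=1) <= r + tol_r
        in_band = (nodes[:, 2] >= z_tip - tol_z) & (nodes[:, 2] <= z_top + tol_z)
        ok = on_cyl & in_band
        tag[np.all(ok[tris], axis=1)] = label
    mesh = Mesh(nodes, tets, tris, tag.astype(str), owner)
    mesh.validate()
    return mesh


def build_plate_box(gap: float = 0.01, area: float = 1e-4,
                    n_gap: int = 4, n_side: int = 4) -> Mesh:
    """Plate-capacitor verification box.

    A rectangular block of tissue between two full-face plate electrodes:
    ``ELECTRODE_A`` at z = gap (driven), ``ELECTRODE_B`` at z = 0 (ground),
    side walls ``OUTER``.  The uniform-field solution is exactly
    representable by linear elements, which makes this the reference
    geometry for analytic cross-checks.
    """
    if gap <= 0 or area <= 0:
        raise MeshError("gap and area must be positive")
    side = float(np.sqrt(area))
    g = np.linspace(0.0, side, n_side + 1)
    gx, gy = np.meshgrid(g, g)
    points2d = np.column_stack([gx.ravel(), gy.ravel()])
    # split each grid quad along the diagonal through its minimum index
    quads = []
    for j in range(n_side):
        for i in range(n_side):
            a = j * (n_side + 1) + i
            b, c, d = a + 1, a + n_side + 2, a + n_side + 1
            quads.append((a, b, c, d))
    tris = []
    for a, b, c, d in quads:
        if min(a, c) < min(b, d):
            tris += [(a, b, c), (a, c, d)]
        else:
            tris += [(a, b, d), (b, c, d)]
    tris = np.array(tris)
    z_levels = np.linspace(0.0, gap, n_gap + 1)
    nodes, tets = _extrude(points2d, [tris] * n_gap, z_levels)
    tris3, owner = _boundary_faces(nodes, tets)
    zc = nodes[tris3, 2].mean(axis=1)
    tag = np.full(len(tris3), OUTER, dtype=object)
    tag[np.abs(zc - gap) < 1e-12 + 1e-9 * gap] = ELECTRODE_A
    tag[np.abs(zc) < 1e-12 + 1e-9 * gap] = ELECTRODE_B
    mesh = Mesh(nodes, tets, tris3, tag.astype(str), owner)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# MSH I/O (ASCII 2.2 and 4.1, named physical groups)

_PHYS = {ELECTRODE_A: 1, ELECTRODE_B: 2, OUTER: 3}
_PHYS_INV = {v: k for k, v in _PHYS.items()}
_TISSUE_PHYS = 4


def write_mesh_msh(mesh: Mesh, path: str | Path, version: str = "2.2") -> None:
    """Write the mesh as Gmsh ASCII, version ``"2.2"`` or ``"4.1"``."""
    if version == "2.2":
        text = _write_msh22(mesh)
    elif version == "4.1":
        text = _write_msh41(mesh)
    else:
        raise MeshFormatError(f"unsupported MSH version {version!r}")
    Path(path).write_text(text)


def _write_msh22(mesh: Mesh) -> str:
    out = io.StringIO()
    out.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    out.write("$PhysicalNames\n4\n")
    for tag, num in _PHYS.items():
        out.write(f'2 {num} "{tag}"\n')
    out.write(f'3 {_TISSUE_PHYS} "tissue"\n$EndPhysicalNames\n')
    out.write(f"$Nodes\n{mesh.n_nodes}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    out.write("$EndNodes\n")
    n_el = len(mesh.tri_nodes) + mesh.n_elements
    out.write(f"$Elements\n{n_el}\n")
    eid = 1
    for tri, tag in zip(mesh.tri_nodes, mesh.tri_tag):
        p = _PHYS[str(tag)]
        out.write(f"{eid} 2 2 {p} {p} {tri[0]+1} {tri[1]+1} {tri[2]+1}\n")
        eid += 1
    for tet in mesh.tets:
        out.write(f"{eid} 4 2 {_TISSUE_PHYS} {_TISSUE_PHYS} "
                  f"{tet[0]+1} {tet[1]+1} {tet[2]+1} {tet[3]+1}\n")
        eid += 1
    out.write("$EndElements\n")
    return out.getvalue()


def _write_msh41(mesh: Mesh) -> str:
    out = io.StringIO()
    out.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    out.write("$PhysicalNames\n4\n")
    for tag, num in _PHYS.items():
        out.write(f'2 {num} "{tag}"\n')
    out.write(f'3 {_TISSUE_PHYS} "tissue"\n$EndPhysicalNames\n')
    # one discrete surface entity per physical group + one volume entity
    out.write("$Entities\n0 0 3 1\n")
    for tag, num in _PHYS.items():
        out.write(f"{num} 0 0 0 0 0 0 1 {num}\n")
    out.write(f"{_TISSUE_PHYS} 0 0 0 0 0 0 1 {_TISSUE_PHYS}\n$EndEntities\n")
    n = mesh.n_nodes
    out.write(f"$Nodes\n1 {n} 1 {n}\n3 1 0 {n}\n")
    for i in range(1, n + 1):
        out.write(f"{i}\n")
    for x, y, z in mesh.nodes:
        out.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    out.write("$EndNodes\n")
    blocks = []
    for tag, num in _PHYS.items():
        idx = mesh.tri_index(str(tag))
        if idx.size:
            blocks.append((2, num, 2, mesh.tri_nodes[idx]))
    blocks.append((3, _TISSUE_PHYS, 4, mesh.tets))
    total = sum(len(b[3]) for b in blocks)
    out.write(f"$Elements\n{len(blocks)} {total} 1 {total}\n")
    eid = 1
    for dim, ent, etype, elems in blocks:
        out.write(f"{dim} {ent} {etype} {len(elems)}\n")
        for row in elems:
            out.write(" ".join([str(eid)] + [str(v + 1) for v in row]) + "\n")
            eid += 1
    out.write("$EndElements\n")
    return out.getvalue()


def _sections(lines: list[str]) -> dict[str, list[str]]:
    sec, name, buf = {}, None, []
    for ln in lines:
        s = ln.strip()
        if s.startswith("$End"):
            sec[name] = buf
            name, buf = None, []
        elif s.startswith("$"):
            name = s[1:]
        elif name is not None:
            buf.append(s)
    return sec


def read_mesh_msh(path: str | Path) -> Mesh:
    """Read a Gmsh ASCII mesh (version 2.2 or 4.1).

    Surface physical groups must be named ``electrode_a``, ``electrode_b``
    and ``outer``; tetrahedra form the tissue volume.  Degenerate (zero or
    negative volume) tetrahedra are rejected with the offending element
    index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sec = _sections(path.read_text().splitlines())
    if "MeshFormat" not in sec:
        raise MeshFormatError(f"{path}: not an MSH file")
    version = sec["MeshFormat"][0].split()[0]
    names = {}
    for ln in sec.get("PhysicalNames", [])[1:]:
        parts = ln.split(maxsplit=2)
        if len(parts) == 3:
            names[int(parts[1])] = parts[2].strip().strip('"')
    if version.startswith("2"):
        nodes, tris, tri_phys, tets = _read_msh22(sec)
    elif version.startswith("4"):
        nodes, tris, tri_phys, tets = _read_msh41(sec)
    else:
        raise MeshFormatError(f"{path}: unsupported MSH version {version}")
    tag_of = {}
    for phys, nm in names.items():
        if nm in _TAGS:
            tag_of[phys] = nm
    missing = [t for t in (ELECTRODE_A, ELECTRODE_B) if t not in tag_of.values()]
    if missing:
        raise MeshFormatError(f"{path}: missing physical groups {missing}")
    vol = _tet_volumes(nodes, tets)
    bad = np.nonzero(vol <= 0)[0]
    if bad.size:
        raise MeshFormatError(f"{path}: degenerate/inverted tetrahedron at element {int(bad[0])}")
    # recompute boundary orientation/ownership; keep file tags by face key
    btris, owner = _boundary_faces(nodes, tets)
    key2tag = {}
    for tri, phys in zip(tris, tri_phys):
        key2tag[tuple(sorted(tri))] = tag_of.get(phys, OUTER)
    tag = np.array([key2tag.get(tuple(sorted(t)), OUTER) for t in btris], dtype=object)
    mesh = Mesh(nodes, tets, btris, tag.astype(str), owner)
    mesh.validate()
    return mesh


def _read_msh22(sec):
    node_lines = sec["Nodes"][1:]
    ids = np.array([int(ln.split()[0]) for ln in node_lines])
    coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in node_lines])
    remap = {nid: k for k, nid in enumerate(ids)}
    tris, tri_phys, tets = [], [], []
    for ln in sec["Elements"][1:]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3:3 + ntags]
        conn = [remap[v] for v in parts[3 + ntags:]]
        if etype == 2:
            tris.append(conn)
            tri_phys.append(tags[0] if tags else 0)
        elif etype == 4:
            tets.append(conn)
    if not tets:
        raise MeshFormatError("no tetrahedra in file")
    return coords, np.array(tris, dtype=np.int64).reshape(-1, 3), \
        np.array(tri_phys, dtype=int), np.array(tets, dtype=np.int64)


def _read_msh41(sec):
    ent_surf = {}
    ent_vol = {}
    if "Entities" in sec:
        it = iter(sec["Entities"])
        np_, nc, ns, nv = (int(v) for v in next(it).split())
        for _ in range(np_ + nc):
            next(it)
        for _ in range(ns):
            parts = next(it).split()
            n_phys = int(parts[7])
            ent_surf[int(parts[0])] = int(parts[8]) if n_phys else 0
        for _ in range(nv):
            parts = next(it).split()
            n_phys = int(parts[7])
            ent_vol[int(parts[0])] = int(parts[8]) if n_phys else 0
    lines = sec["Nodes"]
    n_blocks = int(lines[0].split()[0])
    pos = 1
    ids, coords = [], []
    for _ in range(n_blocks):
        _, _, _, nn = (int(v) for v in lines[pos].split())
        pos += 1
        blk_ids = [int(lines[pos + k]) for k in range(nn)]
        pos += nn
        for k in range(nn):
            coords.append([float(v) for v in lines[pos + k].split()[:3]])
        pos += nn
        ids.extend(blk_ids)
    remap = {nid: k for k, nid in enumerate(ids)}
    nodes = np.array(coords)
    lines = sec["Elements"]
    n_blocks = int(lines[0].split()[0])
    pos = 1
    tris, tri_phys, tets = [], [], []
    for _ in range(n_blocks):
        dim, ent, etype, ne = (int(v) for v in lines[pos].split())
        pos += 1
        for k in range(ne):
            conn = [remap[int(v)] for v in lines[pos + k].split()[1:]]
            if etype == 2:
                tris.append(conn)
                tri_phys.append(ent_surf.get(ent, 0))
            elif etype == 4:
                tets.append(conn)
        pos += ne
    if not tets:
        raise MeshFormatError("no tetrahedra in file")
    return nodes, np.array(tris, dtype=np.int64).reshape(-1, 3), \
        np.array(tri_phys, dtype=int), np.array(tets, dtype=np.int64)


# ---------------------------------------------------------------------------
# VTK export


def write_vtk(mesh: Mesh, path: str | Path,
              cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and per-element/per-node fields as legacy ASCII VTK."""
    out = io.StringIO()
    out.write("# vtk DataFile Version 3.0\nepfem field snapshot\nASCII\n")
    out.write("DATASET UNSTRUCTURED_GRID\n")
    out.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y, z in mesh.nodes:
        out.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    m = mesh.n_elements
    out.write(f"CELLS {m} {5 * m}\n")
    for tet in mesh.tets:
        out.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
    out.write(f"CELL_TYPES {m}\n")
    out.write("\n".join(["10"] * m) + "\n")
    if cell_data:
        out.write(f"CELL_DATA {m}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                out.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                out.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
            else:
                out.write(f"VECTORS {name} double\n")
                for row in arr:
                    out.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
    if point_data:
        out.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            out.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            out.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
    Path(path).write_text(out.getvalue())
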