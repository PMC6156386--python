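"""Biventricular tetrahedral mesh container, validation, partition and I/O.

The mesh is the Lagrangian body of the registration: linear (P1)
tetrahedra carrying reference positions ``X`` in millimetres, boundary
facet tags for the four anatomical surfaces (LV endocardium, RV
endocardium, epicardium, basal truncation plane) and a per-cell region
label (LV free wall, septum, RV free wall).  The deformation gradient is
constant per element, so all strain reporting downstream is per cell.

Region partition follows a Laplace-field rule: two harmonic "distance
like" coordinates are solved (0 on one endocardium, 1 on the
epicardium, natural elsewhere); a cell whose centroid value is below a
threshold in *both* fields lies between the two blood pools and is
septal, everything else goes to the free wall of the nearer
endocardium.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Surface(IntEnum):
    """Boundary facet tags."""

    LV_ENDO = 1
    RV_ENDO = 2
    EPI = 3
    BASE = 4


class Region(IntEnum):
    """Per-cell myocardial region labels."""

    LV_FREE = 1
    SEPTUM = 2
    RV_FREE = 3


#: All four surface tags a biventricular mesh must carry.
REQUIRED_SURFACES = (Surface.LV_ENDO, Surface.RV_ENDO, Surface.EPI, Surface.BASE)


class MeshError(ValueError):
    pass


def _face_key(tri: np.ndarray) -> tuple[int, int, int]:
    a, b, c = sorted(int(v) for v in tri)
    return (a, b, c)


@dataclass
class BivMesh:
    """Tetrahedral biventricular mesh in reference (material) coordinates.

    Parameters
    ----------
    nodes : (n, 3) float array
        Reference positions X in mm.
    cells : (m, 4) int array
        Tetrahedra as node index quadruples, positively oriented.
    boundary_faces : (k, 3) int array
        Boundary triangles (each belonging to exactly one tet).
    face_tags : (k,) int array
        Surface tag per boundary triangle (values of :class:`Surface`).
    region_labels : (m,) int array or None
        Region label per cell (values of :class:`Region`); filled by
        :func:`partition_regions`.
    long_axis : (3,) unit vector
        Apex-to-base direction.
    """

    nodes: np.ndarray
    cells: np.ndarray
    boundary_faces: np.ndarray
    face_tags: np.ndarray
    long_axis: np.ndarray
    region_labels: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- geometry -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_cells(self) -> int:
        return int(self.cells.shape[0])

    def cell_coords(self) -> np.ndarray:
        """(m, 4, 3) nodal coordinates per cell."""
        return self.nodes[self.cells]

    def cell_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (mm^3); positive for valid meshes."""
        if "volumes" not in self._cache:
            x = self.cell_coords()
            e = x[:, 1:] - x[:, :1]
            self._cache["volumes"] = np.einsum(
                "ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])
            ) / 6.0
        return self._cache["volumes"]

    def cell_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.cell_coords().mean(axis=1)
        return self._cache["centroids"]

    def shape_gradients(self) -> np.ndarray:
        """(m, 4, 3) gradients of the P1 shape functions per cell.

        For a P1 tet, grad(N_a) is constant and F = x_nodes^T G with G
        the returned per-cell 4x3 block; used by both the Laplace solver
        and the warping energy.
        """
        if "shape_grads" not in self._cache:
            x = self.cell_coords()  # (m,4,3)
            # rows of D are the edge vectors from node 0; barycentric
            # coordinates satisfy (x - x0) = D^T lam, so grad N_a (a=1..3)
            # are the rows of D^{-T}; grad N_0 = -sum of the others.
            D = x[:, 1:] - x[:, :1]  # (m,3,3)
            g = np.transpose(np.linalg.inv(D), (0, 2, 1))  # (m,3,3)
            g0 = -g.sum(axis=1, keepdims=True)
            self._cache["shape_grads"] = np.concatenate([g0, g], axis=1)
        return self._cache["shape_grads"]

    def surface_nodes(self, tag: int) -> np.ndarray:
        """Sorted unique node indices on the facets carrying ``tag``."""
        faces = self.boundary_faces[self.face_tags == int(tag)]
        return np.unique(faces)

    def invalidate(self) -> None:
        self._cache.clear()

    # -- validation ---------------------------------------------------

    def check(self, require_regions: bool = False) -> None:
        """Raise :class:`MeshError` on any violated structural invariant."""
        if self.n_nodes < 4:
            raise MeshError("mesh needs at least 4 nodes")
        if self.cells.min() < 0 or self.cells.max() >= self.n_nodes:
            raise MeshError("cell connectivity indexes nonexistent nodes")
        vol = self.cell_volumes()
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise MeshError(
                f"non-positive tetrahedron volume (cell {bad}, V={vol[bad]:.3e} mm^3)"
            )
        if self.boundary_faces.shape[0] != self.face_tags.shape[0]:
            raise MeshError("face_tags length must match boundary_faces")
        la = np.asarray(self.long_axis, float)
        if not np.isclose(np.linalg.norm(la), 1.0, atol=1e-8):
            raise MeshError("long_axis must be a unit vector")
        if require_regions:
            if self.region_labels is None:
                raise MeshError("region labels missing")
            if self.region_labels.shape[0] != self.n_cells:
                raise MeshError("region label per cell required")

    def reorient(self) -> int:
        """Flip inverted tetrahedra in place; returns number flipped."""
        vol = self.cell_volumes()
        bad = vol < 0
        if bad.any():
            self.cells[bad, 1], self.cells[bad, 2] = (
                self.cells[bad, 2].copy(),
                self.cells[bad, 1].copy(),
            )
            self.invalidate()
        return int(bad.sum())


def boundary_of(cells: np.ndarray) -> np.ndarray:
    """Boundary triangles (faces owned by exactly one tet), outward oriented."""
    # local faces with outward orientation for a positively oriented tet
    local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([cells[:, f] for f in local], axis=0)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

def partition_regions(
    mesh: BivMesh, septum_threshold: float = 0.5
) -> np.ndarray:
    """Label every cell LV_FREE, SEPTUM or RV_FREE.

    Two harmonic coordinates are solved on the mesh: ``d_LV`` (0 on the
    LV endocardium, 1 on the epicardium) and ``d_RV`` (0 on the RV
    endocardium, 1 on the epicardium), natural boundary conditions
    elsewhere.  The septum is bounded by the two endocardia and far from
    the epicardium, so both fields stay small there; in each free wall
    the field of the *opposite* ventricle is pinned near 1 by the
    epicardium.  A cell is septal when both centroid values are <=
    ``septum_threshold`` (ties go to the septum); otherwise it joins the
    free wall of the nearer endocardium (smaller field value).

    The labels are stored on ``mesh.region_labels`` and returned.
    """
    from .directions import solve_laplace_coordinate  # local import: no cycle at load

    if not set(int(t) for t in np.unique(mesh.face_tags)) >= {
        int(Surface.LV_ENDO),
        int(Surface.RV_ENDO),
        int(Surface.EPI),
    }:
        missing = [
            s.name
            for s in (Surface.LV_ENDO, Surface.RV_ENDO, Surface.EPI)
            if int(s) not in mesh.face_tags
        ]
        raise MeshError(f"partition requires surface tags: missing {missing}")

    d_lv = solve_laplace_coordinate(mesh, {Surface.LV_ENDO: 0.0, Surface.EPI: 1.0})
    d_rv = solve_laplace_coordinate(mesh, {Surface.RV_ENDO: 0.0, Surface.EPI: 1.0})
    # centroid value of a P1 field = mean of its vertex values
    c_lv = d_lv[mesh.cells].mean(axis=1)
    c_rv = d_rv[mesh.cells].mean(axis=1)

    labels = np.full(mesh.n_cells, int(Region.RV_FREE), dtype=np.int32)
    labels[c_lv < c_rv] = int(Region.LV_FREE)
    is_septum = (c_lv <= septum_threshold) & (c_rv <= septum_threshold)
    labels[is_septum] = int(Region.SEPTUM)
    labels = _absorb_stray_components(mesh.cells, labels)

    for r in Region:
        if not np.any(labels == int(r)):
            raise MeshError(f"region {r.name} received zero cells")
    mesh.region_labels = labels
    return labels


def _cell_face_adjacency(cells: np.ndarray):
    import scipy.sparse as sp

    local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([cells[:, f] for f in local], axis=0)
    owner = np.tile(np.arange(len(cells)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key, owner = key[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    i, j = owner[:-1][same], owner[1:][same]
    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(len(cells), len(cells)))
    return (adj + adj.T).tocsr()


def _absorb_stray_components(cells: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel cells outside each region's main component.

    Threshold rules occasionally strand a handful of cells away from
    their region's body (tie-break cells at the horns); they take the
    majority label of their face neighbours so every region is a single
    face-connected component.
    """
    import scipy.sparse.csgraph as csgraph

    adj = _cell_face_adjacency(cells)
    labels = labels.copy()
    for _ in range(10):
        stray = np.zeros(len(cells), dtype=bool)
        for r in np.unique(labels):
            idx = np.flatnonzero(labels == r)
            sub = adj[idx][:, idx]
            n, comp = csgraph.connected_components(sub, directed=False)
            if n > 1:
                main = np.argmax(np.bincount(comp))
                stray[idx[comp != main]] = True
        if not stray.any():
            break
        indptr, indices = adj.indptr, adj.indices
        for ci in np.flatnonzero(stray):
            nb = indices[indptr[ci] : indptr[ci + 1]]
            nb = nb[~stray[nb]]
            if nb.size:
                vals, counts = np.unique(labels[nb], return_counts=True)
                labels[ci] = vals[np.argmax(counts)]
    return labels


def region_connected_components(mesh: BivMesh, region: int) -> int:
    """Number of face-connected components of the cells in ``region``."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    idx = np.flatnonzero(mesh.region_labels == int(region))
    sub = mesh.cells[idx]
    local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([sub[:, f] for f in local], axis=0)
    owner = np.tile(np.arange(len(idx)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key, owner = key[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=0 if key.ndim == 1 else 1)
    i, j = owner[:-1][same], owner[1:][same]
    adj = sp.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(len(idx), len(idx))
    )
    n, _ = csgraph.connected_components(adj + adj.T, directed=False)
    return int(n)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

def validate_mesh(mesh: BivMesh) -> dict:
    """Report-only quality summary: volumes, aspect ratios, counts, closure."""
    vol = mesh.cell_volumes()
    x = mesh.cell_coords()
    # aspect ratio: longest edge / (6*sqrt(2)*V / max-face-area) ~ use edge/inradius proxy
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(x[:, a] - x[:, b], axis=1) for a, b in pairs], 1)
    lmax = edges.max(axis=1)
    # inradius r = 3V / total face area
    def tri_area(p, q, r):
        return 0.5 * np.linalg.norm(np.cross(q - p, r - p), axis=1)

    area = (
        tri_area(x[:, 0], x[:, 1], x[:, 2])
        + tri_area(x[:, 0], x[:, 1], x[:, 3])
        + tri_area(x[:, 0], x[:, 2], x[:, 3])
        + tri_area(x[:, 1], x[:, 2], x[:, 3])
    )
    inradius = 3.0 * np.abs(vol) / area
    aspect = lmax / np.maximum(inradius, 1e-300)

    # closure: every edge of the boundary triangulation shared by exactly 2 faces
    bf = mesh.boundary_faces
    ed = np.concatenate([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [2, 0]]], axis=0)
    ed = np.sort(ed, axis=1)
    _, counts = np.unique(ed, axis=0, return_counts=True)
    closed = bool(np.all(counts == 2))

    report = {
        "n_nodes": mesh.n_nodes,
        "n_cells": mesh.n_cells,
        "min_volume": float(vol.min()),
        "max_volume": float(vol.max()),
        "total_volume": float(vol.sum()),
        "n_degenerate": int(np.sum(vol <= 0)),
        "max_aspect_ratio": float(aspect.max()),
        "median_aspect_ratio": float(np.median(aspect)),
        "surface_closed": closed,
        "face_tag_counts": {
            (Surface(t).name if int(t) in Surface._value2member_map_ else str(int(t))): int(
                np.sum(mesh.face_tags == t)
            )
            for t in np.unique(mesh.face_tags)
        },
    }
    if mesh.region_labels is not None:
        report["region_cell_counts"] = {
            Region(r).name: int(np.sum(mesh.region_labels == r))
            for r in np.unique(mesh.region_labels)
        }
    return report


# ---------------------------------------------------------------------------
# Structured verification meshes (slab / spherical shell / cylinder shell)
# ---------------------------------------------------------------------------

_KUHN = [
    (0, 1, 3, 7),
    (0, 1, 7, 5),
    (0, 5, 7, 4),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
]


def _hex_grid_to_tets(shape: tuple[int, int, int]) -> np.ndarray:
    """Kuhn split of a structured (ni,nj,nk)-node hex grid into tets."""
    ni, nj, nk = shape
    idx = np.arange(ni * nj * nk).reshape(ni, nj, nk)
    c = np.empty((ni - 1, nj - 1, nk - 1, 8), dtype=np.int64)
    c[..., 0] = idx[:-1, :-1, :-1]
    c[..., 1] = idx[1:, :-1, :-1]
    c[..., 2] = idx[:-1, 1:, :-1]
    c[..., 3] = idx[1:, 1:, :-1]
    c[..., 4] = idx[:-1, :-1, 1:]
    c[..., 5] = idx[1:, :-1, 1:]
    c[..., 6] = idx[:-1, 1:, 1:]
    c[..., 7] = idx[1:, 1:, 1:]
    c = c.reshape(-1, 8)
    return np.concatenate([c[:, t] for t in _KUHN], axis=0)


def slab_mesh(
    lx: float = 1.0,
    ly: float = 1.0,
    lz: float = 1.0,
    n: int = 6,
    tag_axis: int = 2,
    tag_lo: int = Surface.LV_ENDO,
    tag_hi: int = Surface.EPI,
) -> BivMesh:
    """Structured tet mesh of a box; opposite faces along ``tag_axis`` tagged.

    Verification geometry for the Laplace solver (harmonic ramp between
    the two tagged faces).
    """
    xs = [np.linspace(0, L, n + 1) for L in (lx, ly, lz)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    cells = _hex_grid_to_tets((n + 1, n + 1, n + 1))
    faces = boundary_of(cells)
    fc = nodes[faces].mean(axis=1)
    L = (lx, ly, lz)[tag_axis]
    tags = np.full(len(faces), int(Surface.BASE), dtype=np.int32)
    tags[np.isclose(fc[:, tag_axis], 0.0)] = int(tag_lo)
    tags[np.isclose(fc[:, tag_axis], L)] = int(tag_hi)
    m = BivMesh(nodes, cells, faces, tags, np.array([0.0, 0.0, 1.0]))
    m.reorient()
    return m


def spherical_shell_mesh(a: float, b: float, n_r: int, n_ang: int) -> BivMesh:
    """Structured tet mesh of the shell a<=r<=b (inner tag LV_ENDO, outer EPI).

    Built by mapping a lat/long grid; poles are collapsed, so use the
    returned mesh for scalar-field verification (Laplace) only.
    """
    r = np.linspace(a, b, n_r + 1)
    th = np.linspace(0.2, np.pi - 0.2, n_ang + 1)  # keep off the poles
    ph = np.linspace(0.0, 2 * np.pi, 2 * n_ang + 1)[:-1]
    R, T, P = np.meshgrid(r, th, ph, indexing="ij")
    nodes = np.stack(
        [
            (R * np.sin(T) * np.cos(P)).ravel(),
            (R * np.sin(T) * np.sin(P)).ravel(),
            (R * np.cos(T)).ravel(),
        ],
        axis=1,
    )
    nr, nt, npp = n_r + 1, n_ang + 1, 2 * n_ang
    idx = np.arange(nr * nt * npp).reshape(nr, nt, npp)
    idx = np.concatenate([idx, idx[:, :, :1]], axis=2)  # periodic in phi
    c = np.empty((n_r, n_ang, npp, 8), dtype=np.int64)
    c[..., 0] = idx[:-1, :-1, :-1]
    c[..., 1] = idx[1:, :-1, :-1]
    c[..., 2] = idx[:-1, 1:, :-1]
    c[..., 3] = idx[1:, 1:, :-1]
    c[..., 4] = idx[:-1, :-1, 1:]
    c[..., 5] = idx[1:, :-1, 1:]
    c[..., 6] = idx[:-1, 1:, 1:]
    c[..., 7] = idx[1:, 1:, 1:]
    c = c.reshape(-1, 8)
    cells = np.concatenate([c[:, t] for t in _KUHN], axis=0)
    faces = boundary_of(cells)
    fr = np.linalg.norm(nodes[faces].mean(axis=1), axis=1)
    tags = np.full(len(faces), int(Surface.BASE), dtype=np.int32)
    tags[fr < a + 0.25 * (b - a) / n_r] = int(Surface.LV_ENDO)
    tags[fr > b - 0.25 * (b - a) / n_r] = int(Surface.EPI)
    m = BivMesh(nodes, cells, faces, tags, np.array([0.0, 0.0, 1.0]))
    m.reorient()
    return m


def cylinder_shell_mesh(
    a: float, b: float, height: float, n_r: int, n_th: int, n_z: int
) -> BivMesh:
    """Structured tet mesh of an annular cylinder along z.

    Inner surface tagged LV_ENDO, outer EPI, top (z=height) BASE; the
    bottom stays untagged.  Used to verify the rule-based direction
    triads against the analytic cylindrical frame.
    """
    r = np.linspace(a, b, n_r + 1)
    th = np.linspace(0, 2 * np.pi, n_th + 1)[:-1]
    z = np.linspace(0, height, n_z + 1)
    R, T, Z = np.meshgrid(r, th, z, indexing="ij")
    nodes = np.stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()], axis=1
    )
    nr, nt, nz = n_r + 1, n_th, n_z + 1
    idx = np.arange(nr * nt * nz).reshape(nr, nt, nz)
    idx = np.concatenate([idx, idx[:, :1, :]], axis=1)  # periodic in theta
    c = np.empty((n_r, nt, n_z, 8), dtype=np.int64)
    c[..., 0] = idx[:-1, :-1, :-1]
    c[..., 1] = idx[1:, :-1, :-1]
    c[..., 2] = idx[:-1, 1:, :-1]
    c[..., 3] = idx[1:, 1:, :-1]
    c[..., 4] = idx[:-1, :-1, 1:]
    c[..., 5] = idx[1:, :-1, 1:]
    c[..., 6] = idx[:-1, 1:, 1:]
    c[..., 7] = idx[1:, 1:, 1:]
    c = c.reshape(-1, 8)
    cells = np.concatenate([c[:, t] for t in _KUHN], axis=0)
    faces = boundary_of(cells)
    fc = nodes[faces].mean(axis=1)
    fr = np.hypot(fc[:, 0], fc[:, 1])
    tags = np.zeros(len(faces), dtype=np.int32)
    dr = (b - a) / n_r
    tags[fr < a + 0.25 * dr] = int(Surface.LV_ENDO)
    tags[fr > b - 0.25 * dr] = int(Surface.EPI)
    tags[np.isclose(fc[:, 2], height)] = int(Surface.BASE)
    m = BivMesh(nodes, cells, faces, tags, np.array([0.0, 0.0, 1.0]))
    m.reorient()
    return m


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII and legacy VTK I/O
# ---------------------------------------------------------------------------
# Physical groups: surfaces use the Surface tag values, volume regions use
# 100 + Region value so the two tag spaces cannot collide.

_REGION_PHYS_OFFSET = 100


def write_msh(mesh: BivMesh, path) -> None:
    """Write Gmsh MSH 2.2 ASCII with physical groups for tags and regions."""
    buf = _io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write(f"$Nodes\n{mesh.n_nodes}\n")
    for i, p in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    buf.write("$EndNodes\n")
    n_elem = mesh.n_cells + len(mesh.boundary_faces)
    buf.write(f"$Elements\n{n_elem}\n")
    eid = 1
    for f, t in zip(mesh.boundary_faces, mesh.face_tags):
        buf.write(
            f"{eid} 2 2 {int(t)} {int(t)} {f[0]+1} {f[1]+1} {f[2]+1}\n"
        )
        eid += 1
    labels = (
        mesh.region_labels
        if mesh.region_labels is not None
        else np.zeros(mesh.n_cells, dtype=int)
    )
    for c, r in zip(mesh.cells, labels):
        phys = _REGION_PHYS_OFFSET + int(r)
        buf.write(
            f"{eid} 4 2 {phys} {phys} {c[0]+1} {c[1]+1} {c[2]+1} {c[3]+1}\n"
        )
        eid += 1
    buf.write("$EndElements\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_msh(path, tag_map: dict | None = None) -> BivMesh:
    """Read a Gmsh MSH 2.2 ASCII file written by :func:`write_msh`.

    ``tag_map`` optionally remaps physical-group ids of the surface
    triangles onto :class:`Surface` values.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        i_nodes = lines.index("$Nodes")
        i_elems = lines.index("$Elements")
    except ValueError as e:
        raise MeshError(f"not a MSH 2.2 ASCII file: {path}") from e
    n_nodes = int(lines[i_nodes + 1])
    nodes = np.loadtxt(
        _io.StringIO("\n".join(lines[i_nodes + 2 : i_nodes + 2 + n_nodes]))
    ).reshape(n_nodes, 4)[:, 1:]
    n_elem = int(lines[i_elems + 1])
    tris, tri_tags, tets, tet_regions = [], [], [], []
    for ln in lines[i_elems + 2 : i_elems + 2 + n_elem]:
        parts = ln.split()
        etype = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags else 0
        conn = [int(v) - 1 for v in parts[3 + ntags :]]
        if etype == 2:
            tris.append(conn)
            tri_tags.append(phys)
        elif etype == 4:
            tets.append(conn)
            tet_regions.append(phys - _REGION_PHYS_OFFSET)
    tri_tags = np.asarray(tri_tags, dtype=np.int32)
    if tag_map:
        remapped = tri_tags.copy()
        for src, dst in tag_map.items():
            remapped[tri_tags == int(src)] = int(dst)
        tri_tags = remapped
    present = set(int(t) for t in np.unique(tri_tags))
    missing = [s.name for s in REQUIRED_SURFACES if int(s) not in present]
    if missing:
        raise MeshError(f"mesh file lacks required surface tag(s): {missing}")
    regions = np.asarray(tet_regions, dtype=np.int32)
    mesh = BivMesh(
        nodes=np.asarray(nodes, float),
        cells=np.asarray(tets, dtype=np.int64),
        boundary_faces=np.asarray(tris, dtype=np.int64),
        face_tags=tri_tags,
        long_axis=np.array([0.0, 0.0, 1.0]),
        region_labels=regions if np.all(regions > 0) else None,
    )
    mesh.reorient()
    mesh.check()
    return mesh


def write_vtk(
    mesh: BivMesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write legacy VTK ASCII (unstructured grid) for visual audit."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardiowarp mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {mesh.n_cells} {mesh.n_cells * 5}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(mesh.n_cells, 4), mesh.cells]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {mesh.n_cells}\n")
        np.savetxt(fh, np.full(mesh.n_cells, 10), fmt="%d")
        cd = dict(cell_data or {})
        if mesh.region_labels is not None and "region" not in cd:
            cd["region"] = mesh.region_labels
        if cd:
            fh.write(f"CELL_DATA {mesh.n_cells}\n")
            for name, arr in cd.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                    fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%d" if dtype == "int" else "%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr.reshape(len(arr), -1)[:, :3], fmt="%.9g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")


def read_vtk(path) -> BivMesh:
    """Read a legacy VTK ASCII file written by :func:`write_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        try:
            return tokens.index(word)
        except ValueError as e:
            raise MeshError(f"corrupt VTK file {path}: missing {word}") from e

    i = find("POINTS")
    n = int(tokens[i + 1])
    nodes = np.array(tokens[i + 3 : i + 3 + 3 * n], float).reshape(n, 3)
    i = find("CELLS")
    m = int(tokens[i + 1])
    raw = np.array(tokens[i + 3 : i + 3 + 5 * m], dtype=np.int64).reshape(m, 5)
    cells = raw[:, 1:]
    regions = None
    if "region" in tokens:
        i = tokens.index("region")
        # SCALARS region int 1 LOOKUP_TABLE default <values...>
        regions = np.array(tokens[i + 5 : i + 5 + m], dtype=np.int32)
    faces = boundary_of(cells)
    # legacy VTK from this package carries no facet tags; re-derive from file pairing
    mesh = BivMesh(
        nodes=nodes,
        cells=cells,
        boundary_faces=faces,
        face_tags=np.zeros(len(faces), dtype=np.int32),
        long_axis=np.array([0.0, 0.0, 1.0]),
        region_labels=regions,
    )
    mesh.reorient()
    return mesh


def import_mesh(path, tag_map: dict | None = None) -> BivMesh:
    """Import a biventricular mesh (MSH 2.2 preferred; VTK for geometry only)."""
    p = str(path)
    if p.endswith(".msh"):
        return read_msh(p, tag_map)
    if p.endswith(".vtk"):
        return read_vtk(p)
    raise MeshError(f"unsupported mesh format: {p}")
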