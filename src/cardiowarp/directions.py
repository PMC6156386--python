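"""Rule-based local cardiac coordinate triads from harmonic fields.

Per-element circumferential / longitudinal / radial unit vectors
(e_C, e_L, e_R) are constructed Laplace-Dirichlet style: harmonic scalar
coordinates are solved on the tetrahedral mesh with Dirichlet data on
the tagged anatomical surfaces and natural (zero-flux) conditions
elsewhere, and the triads are assembled from their per-cell gradients.
The myofiber angle is identically zero, so the triad IS the
structural frame:

* e_R  — normalized gradient of a transmural coordinate, pointing
  endocardium -> epicardium in the free walls and LV -> RV across the
  septum;
* e_L  — gradient of an apicobasal coordinate, orthogonalized against
  e_R and oriented apex -> base;
* e_C  — e_L x e_R, closing a right-handed orthonormal triad.

Two transmural fields are used (one per ventricle) because a single
field clamped to zero on both endocardia would peak inside the septum
and its gradient would vanish there; each cell takes the field of the
ventricle it belongs to (LV field covers the septum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import BivMesh, Region, Surface


class DirectionsError(ValueError):
    pass


@dataclass
class DirectionField:
    """Per-cell orthonormal triads; rows of each array are unit vectors."""

    e_c: np.ndarray  # (m,3) circumferential
    e_l: np.ndarray  # (m,3) longitudinal
    e_r: np.ndarray  # (m,3) radial

    def triads(self) -> np.ndarray:
        """(m, 3, 3) arrays with columns (e_C, e_L, e_R)."""
        return np.stack([self.e_c, self.e_l, self.e_r], axis=2)

    def check(self, norm_tol: float = 1e-10, ortho_tol: float = 1e-8) -> None:
        for name, e in (("e_C", self.e_c), ("e_L", self.e_l), ("e_R", self.e_r)):
            err = np.abs(np.linalg.norm(e, axis=1) - 1.0).max()
            if err > norm_tol:
                raise DirectionsError(f"{name} not unit norm (max err {err:.2e})")
        for a, b, nm in (
            (self.e_c, self.e_l, "e_C.e_L"),
            (self.e_c, self.e_r, "e_C.e_R"),
            (self.e_l, self.e_r, "e_L.e_R"),
        ):
            err = np.abs(np.einsum("ij,ij->i", a, b)).max()
            if err > ortho_tol:
                raise DirectionsError(f"triad not orthogonal: {nm} = {err:.2e}")
        det = np.linalg.det(self.triads())
        if np.any(det < 0.5):
            raise DirectionsError("triad not right-handed")


# ---------------------------------------------------------------------------
# P1 Laplace solver
# ---------------------------------------------------------------------------

def _stiffness(mesh: BivMesh) -> sp.csr_matrix:
    G = mesh.shape_gradients()  # (m,4,3)
    V = mesh.cell_volumes()  # (m,)
    Ke = np.einsum("maj,mbj,m->mab", G, G, V)  # (m,4,4)
    rows = np.repeat(mesh.cells, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.cells, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (Ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def solve_laplace_coordinate(
    mesh: BivMesh,
    dirichlet_tags: dict | None = None,
    dirichlet_nodes: dict | None = None,
) -> np.ndarray:
    """Solve Laplace's equation with P1 elements on the mesh.

    Parameters
    ----------
    dirichlet_tags : mapping surface tag -> value
        Every node on a facet carrying the tag is clamped to the value.
    dirichlet_nodes : mapping value -> node index array (optional)
        Extra point-wise Dirichlet patches (e.g. an apex point region).

    Returns
    -------
    (n_nodes,) nodal field; values are bounded by the Dirichlet extremes
    (discrete maximum principle holds for the P1 stiffness as long as
    the mesh is not grossly obtuse).
    """
    fixed_idx: list[np.ndarray] = []
    fixed_val: list[np.ndarray] = []
    for tag, value in (dirichlet_tags or {}).items():
        nodes = mesh.surface_nodes(int(tag))
        if nodes.size == 0:
            raise DirectionsError(
                f"no facets tagged {Surface(int(tag)).name} on this mesh"
            )
        fixed_idx.append(nodes)
        fixed_val.append(np.full(nodes.size, float(value)))
    for value, nodes in (dirichlet_nodes or {}).items():
        nodes = np.asarray(nodes, dtype=np.int64)
        fixed_idx.append(nodes)
        fixed_val.append(np.full(nodes.size, float(value)))
    if not fixed_idx:
        raise DirichletMissingError("Laplace solve needs at least one Dirichlet set")
    idx = np.concatenate(fixed_idx)
    val = np.concatenate(fixed_val)
    # later entries win on duplicates
    fixed = np.full(mesh.n_nodes, np.nan)
    fixed[idx] = val
    is_fixed = ~np.isnan(fixed)

    K = _stiffness(mesh)
    u = np.zeros(mesh.n_nodes)
    u[is_fixed] = fixed[is_fixed]
    free = np.flatnonzero(~is_fixed)
    if free.size:
        rhs = -K[free][:, is_fixed] @ u[is_fixed]
        Kff = K[free][:, free]
        u[free] = spla.spsolve(Kff.tocsc(), rhs)
    return u


class DirichletMissingError(DirectionsError):
    pass


def cell_gradient(mesh: BivMesh, field: np.ndarray) -> np.ndarray:
    """Per-cell gradient of a P1 nodal field, (m, 3)."""
    G = mesh.shape_gradients()
    return np.einsum("ma,maj->mj", field[mesh.cells], G)


def smoothed_cell_gradient(mesh: BivMesh, field: np.ndarray) -> np.ndarray:
    """Per-cell gradient recovered through volume-weighted nodal averaging.

    The raw P1 gradient is exactly constant on a cell, so a flat cell
    whose four vertices all lie on one Dirichlet surface carries a zero
    gradient.  Scattering cell gradients to the vertices (weighted by
    cell volume) and gathering them back spreads transmural information
    across such single-layer artifacts — the usual superconvergent
    patch-recovery trick.
    """
    g = cell_gradient(mesh, field)
    V = mesh.cell_volumes()
    acc = np.zeros((mesh.n_nodes, 3))
    wgt = np.zeros(mesh.n_nodes)
    np.add.at(acc, mesh.cells.reshape(-1), np.repeat(g * V[:, None], 4, axis=0))
    np.add.at(wgt, mesh.cells.reshape(-1), np.repeat(V, 4))
    nodal = acc / np.maximum(wgt, 1e-300)[:, None]
    return nodal[mesh.cells].mean(axis=1)


def _fill_weak_cells(
    mesh: BivMesh, g: np.ndarray, tol: float = 1e-12, max_pass: int = 10
) -> np.ndarray:
    """Flood-fill near-zero cell vectors from their vertex neighbours.

    Wall regions pinching to a single flat element layer (e.g. the
    crescent horns) can leave patches where a harmonic coordinate is
    exactly constant; those cells inherit the volume-weighted average
    direction of their nearest resolved neighbours.
    """
    g = g.copy()
    V = mesh.cell_volumes()
    for _ in range(max_pass):
        weak = np.linalg.norm(g, axis=1) < tol
        if not weak.any():
            return g
        acc = np.zeros((mesh.n_nodes, 3))
        wgt = np.zeros(mesh.n_nodes)
        ok = ~weak
        cells_ok = mesh.cells[ok]
        np.add.at(
            acc, cells_ok.reshape(-1), np.repeat(g[ok] * V[ok, None], 4, axis=0)
        )
        np.add.at(wgt, cells_ok.reshape(-1), np.repeat(V[ok], 4))
        nodal = acc / np.maximum(wgt, 1e-300)[:, None]
        g[weak] = nodal[mesh.cells[weak]].mean(axis=1)
    return g


def apex_nodes(mesh: BivMesh, fraction: float = 0.02) -> np.ndarray:
    """Node indices of the apex point-region.

    The apex carries no facet tag, so the lowest ``fraction`` of nodes
    along the long axis (apex -> base projection) forms a point-wise
    Dirichlet patch for the apicobasal field — the usual workaround in
    rule-based direction algorithms.
    """
    proj = mesh.nodes @ np.asarray(mesh.long_axis, float)
    lo, hi = proj.min(), proj.max()
    return np.flatnonzero(proj <= lo + fraction * (hi - lo))


def build_directions(mesh: BivMesh, apex_fraction: float = 0.02) -> DirectionField:
    """Assemble per-cell (e_C, e_L, e_R) triads from harmonic coordinates.

    Requires facet tags; uses region labels when present to pick the
    transmural field per cell (LV field for LV free wall + septum, RV
    field for the RV free wall).  Meshes without an RV endocardium
    (single-ventricle verification geometries) fall back to the single
    LV transmural field.
    """
    tags_present = set(int(t) for t in np.unique(mesh.face_tags))
    has_rv = int(Surface.RV_ENDO) in tags_present
    for required in (Surface.LV_ENDO, Surface.EPI, Surface.BASE):
        if int(required) not in tags_present:
            raise DirectionsError(f"missing surface tag {required.name}")

    if has_rv:
        t_lv = solve_laplace_coordinate(
            mesh, {Surface.LV_ENDO: 0.0, Surface.RV_ENDO: 1.0, Surface.EPI: 1.0}
        )
        t_rv = solve_laplace_coordinate(
            mesh, {Surface.RV_ENDO: 0.0, Surface.LV_ENDO: 1.0, Surface.EPI: 1.0}
        )
        g_lv = smoothed_cell_gradient(mesh, t_lv)
        g_rv = smoothed_cell_gradient(mesh, t_rv)
        if mesh.region_labels is None:
            from .mesh import partition_regions

            partition_regions(mesh)
        use_rv = mesh.region_labels == int(Region.RV_FREE)
        g_t = np.where(use_rv[:, None], g_rv, g_lv)
        # single-layer cells with every node on an equal-value Dirichlet
        # surface have an exactly constant field; fall back to the other
        # ventricle's transmural field there
        weak = np.linalg.norm(g_t, axis=1) < 1e-12
        if weak.any():
            alt = np.where(use_rv[:, None], g_lv, g_rv)
            g_t[weak] = alt[weak]
    else:
        t_lv = solve_laplace_coordinate(
            mesh, {Surface.LV_ENDO: 0.0, Surface.EPI: 1.0}
        )
        g_t = smoothed_cell_gradient(mesh, t_lv)

    g_t = _fill_weak_cells(mesh, g_t)
    norm_r = np.linalg.norm(g_t, axis=1)
    if np.any(norm_r < 1e-12):
        bad = int(np.argmin(norm_r))
        raise DirectionsError(
            f"transmural gradient vanishes in cell {bad}; cannot orient e_R"
        )
    e_r = g_t / norm_r[:, None]

    apicobasal = solve_laplace_coordinate(
        mesh,
        {Surface.BASE: 1.0},
        dirichlet_nodes={0.0: apex_nodes(mesh, apex_fraction)},
    )
    g_l = _fill_weak_cells(mesh, smoothed_cell_gradient(mesh, apicobasal))
    g_l = g_l - np.einsum("ij,ij->i", g_l, e_r)[:, None] * e_r
    norm_l = np.linalg.norm(g_l, axis=1)
    if np.any(norm_l < 1e-12):
        bad = int(np.argmin(norm_l))
        raise DirectionsError(
            f"apicobasal gradient parallel to e_R in cell {bad}; cannot orient e_L"
        )
    e_l = g_l / norm_l[:, None]
    # orient apex -> base
    la = np.asarray(mesh.long_axis, float)
    flip = (e_l @ la) < 0
    e_l[flip] *= -1.0

    e_c = np.cross(e_l, e_r)
    e_c /= np.linalg.norm(e_c, axis=1)[:, None]

    field = DirectionField(e_c=e_c, e_l=e_l, e_r=e_r)
    field.check()
    return field
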