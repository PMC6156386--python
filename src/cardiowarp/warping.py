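"""Hyperelastic warping: intensity-driven FE registration of the heart.

The finite-element body (the biventricular mesh built at end-systole)
is deformed through the cine frames by minimizing, per frame,

    E(phi) = int W(X, C) dv + int (gamma/2) (R(X) - T(phi(X)))^2 dv

where phi(X) = X + u(X) is the mapping, F = dphi/dX, C = F^T F,
W(X, C) = C1 (I1 - 3) is a Neo-Hookean strain energy regularizing the
deformation, R the template intensities (the ES frame sampled once on
the undeformed mesh) and T the target frame sampled at the mapped
points.  The image mismatch enters as a penalty to be minimized with
weight gamma; the image force on the mesh is proportional to the
intensity difference times the target intensity gradient.

A prescribed longitudinal displacement of the basal nodes (amplitude
MAPSE, sinusoidal in time) supplies the through-plane motion the
short-axis stack cannot see.  Minimization uses a feasibility-
preserving L-BFGS with backtracking line search: any step that inverts
an element (J <= 0) is rejected, so the per-frame energy sequence is
non-increasing and the accepted deformation stays locally injective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh import BivMesh, Surface


class WarpError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cycle phase
# ---------------------------------------------------------------------------

def cycle_phase(frame, n_frames: int, es_index: int, ed_index: int = 0) -> np.ndarray:
    """Smooth periodic contraction phase: 0 at ED, 1 at ES.

    A piecewise sin^2 law: phase rises over the ED->ES arc and falls
    back over ES->ED, reducing to sin^2(pi * t/T) when ES sits at
    mid-cycle.  This is the profile driving both the phantom motion and
    the basal boundary condition.
    """
    frame = np.asarray(frame, dtype=float)
    t = ((frame - ed_index) % n_frames) / n_frames
    es = ((es_index - ed_index) % n_frames) / n_frames
    if not 0 < es < 1:
        raise WarpError("es_index must differ from ed_index modulo the cycle")
    rising = np.sin(0.5 * np.pi * t / es) ** 2
    falling = np.sin(0.5 * np.pi * (1.0 - t) / (1.0 - es)) ** 2
    return np.where(t <= es, rising, falling)


# ---------------------------------------------------------------------------
# Image series
# ---------------------------------------------------------------------------

@dataclass
class ImageSeries:
    """Cine volume stack on a common voxel-to-world affine (mm).

    ``frames`` has shape (T, nx, ny, nz); intensities are expected in
    [0, 1] after :func:`normalize_series`.
    """

    frames: np.ndarray
    affine: np.ndarray
    frame_times: np.ndarray
    es_index: int
    ed_index: int
    normalization: dict | None = None
    _smooth_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 4 or self.frames.shape[0] < 2:
            raise WarpError("ImageSeries needs at least 2 frames of 3D volumes")
        if self.es_index == self.ed_index:
            raise WarpError("es_index must differ from ed_index")
        A = np.asarray(self.affine, float)
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise WarpError("image affine is singular")
        self.affine = A

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def voxel_spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        A = self.affine
        return (pts - A[:3, 3]) @ np.linalg.inv(A[:3, :3]).T

    def smoothed(self, frame: int, sd_mm) -> np.ndarray:
        """Gaussian-presmoothed frame; ``sd_mm`` is scalar or per-axis (mm)."""
        sd = np.broadcast_to(np.asarray(sd_mm, float), (3,))
        key = (int(frame), tuple(sd))
        if key not in self._smooth_cache:
            vol = self.frames[frame]
            if np.any(sd > 0):
                sigma = sd / self.voxel_spacing
                vol = ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")
            self._smooth_cache[key] = np.ascontiguousarray(vol)
        return self._smooth_cache[key]


def normalize_series(
    frames: np.ndarray,
    affine: np.ndarray,
    frame_times: np.ndarray,
    es_index: int,
    ed_index: int,
    p_lo: float = 1.0,
    p_hi: float = 99.0,
) -> ImageSeries:
    """Linearly rescale a raw stack so series-wide percentiles hit [0, 1].

    The 1st and 99th intensity percentiles of the WHOLE series map to 0
    and 1, then values are clipped; a constant series is rejected.  The
    scaling record is kept on the result for audit.
    """
    frames = np.asarray(frames, float)
    lo = float(np.percentile(frames, p_lo))
    hi = float(np.percentile(frames, p_hi))
    if hi - lo < 1e-12:
        raise WarpError("cannot normalize: series is (nearly) constant")
    out = np.clip((frames - lo) / (hi - lo), 0.0, 1.0)
    return ImageSeries(
        frames=out,
        affine=affine,
        frame_times=np.asarray(frame_times, float),
        es_index=int(es_index),
        ed_index=int(ed_index),
        normalization={"p_lo": p_lo, "p_hi": p_hi, "lo": lo, "hi": hi},
    )


def sample_image(
    series: ImageSeries, frame: int, world_points: np.ndarray, smoothing_sd: float = 0.0
):
    """Trilinear intensity and its exact spatial gradient at world points.

    The volume is optionally Gaussian-presmoothed (sd in mm); the
    returned gradient is the analytic gradient of the trilinear
    interpolant itself (piecewise multilinear), so assembled energy
    gradients match finite differences to machine-level accuracy.
    Points outside the grid return intensity 0 and a zero gradient.
    """
    vol = series.smoothed(frame, smoothing_sd)
    pts = np.atleast_2d(np.asarray(world_points, float))
    if not np.all(np.isfinite(pts)):
        raise WarpError("sample points must be finite")
    q = series.world_to_index(pts)
    nx, ny, nz = vol.shape
    inside = np.all((q >= 0.0) & (q <= np.array([nx - 1, ny - 1, nz - 1])), axis=1)

    qc = np.clip(q, 0.0, np.array([nx - 1, ny - 1, nz - 1]) - 1e-9)
    i0 = qc.astype(np.int64)
    f = qc - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    c = np.empty((len(pts), 2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = vol[ix + dx, iy + dy, iz + dz]

    wx = np.stack([1 - fx, fx], 1)
    wy = np.stack([1 - fy, fy], 1)
    wz = np.stack([1 - fz, fz], 1)
    dwx = np.stack([-np.ones_like(fx), np.ones_like(fx)], 1)

    val = np.einsum("na,nb,nc,nabc->n", wx, wy, wz, c)
    gx = np.einsum("na,nb,nc,nabc->n", dwx, wy, wz, c)
    gy = np.einsum("na,nb,nc,nabc->n", wx, dwx, wz, c)
    gz = np.einsum("na,nb,nc,nabc->n", wx, wy, dwx, c)
    grad_idx = np.stack([gx, gy, gz], axis=1)
    grad = grad_idx @ np.linalg.inv(series.affine[:3, :3])

    val = np.where(inside, val, 0.0)
    grad[~inside] = 0.0
    return val, grad


# ---------------------------------------------------------------------------
# Config / solution containers
# ---------------------------------------------------------------------------

@dataclass
class WarpConfig:
    """Tunable parameters of the registration.

    c1 : Neo-Hookean (isochoric) modulus, per unit intensity^2 scale.
    kappa : volumetric modulus of the decoupled regularizer.
        Balances regularization against the image term; with intensities
        on [0, 1] and the penalty gamma of 0.005, 1e-4 keeps the elastic
        cost of physiological deformations well below the
        wall-misalignment signal while still damping noise-scale
        displacement wiggles.
    gamma : image mismatch penalty factor (0.005 for all cases).
    mapse : basal longitudinal excursion amplitude in mm.
    """

    c1: float = 1e-4
    kappa: float = 1e-4
    gamma: float = 0.005
    mapse: float = 0.0
    bc_profile: str = "sin2"
    tol: float = 1e-6
    max_iter: int = 200
    smoothing_sd: float = 1.5
    quadrature: str = "sub8"
    lbfgs_memory: int = 8
    volume_weighted_regions: bool = False
    peak_window: str = "systole"

    def __post_init__(self):
        if self.c1 <= 0 or self.gamma <= 0 or self.kappa < 0:
            raise WarpError("C1 and gamma must be positive, kappa non-negative")
        if self.tol <= 0 or self.max_iter <= 0:
            raise WarpError("optimizer tolerances must be positive")
        if self.mapse < 0:
            raise WarpError("mapse must be non-negative")


@dataclass
class MotionSolution:
    """Per-frame tracking result, all relative to the ES configuration.

    ``u`` is (T, n_nodes, 3) nodal displacement (zero at the ES frame),
    ``F`` is (T, n_cells, 3, 3).  Jacobians, Cauchy-Green tensors and
    the first invariant derive from F on demand.
    """

    mesh: BivMesh
    u: np.ndarray
    F: np.ndarray
    energies: np.ndarray
    iteration_log: list
    es_index: int
    ed_index: int
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.u.shape[0])

    def jacobians(self) -> np.ndarray:
        return np.linalg.det(self.F)

    def cauchy_green(self) -> np.ndarray:
        return np.einsum("tmki,tmkj->tmij", self.F, self.F)

    def first_invariant(self) -> np.ndarray:
        return np.einsum("tmkk->tm", self.cauchy_green())

    def mapping(self, frame: int) -> np.ndarray:
        """phi(X) = X + u(X) at a frame."""
        return self.mesh.nodes + self.u[frame]


# ---------------------------------------------------------------------------
# Energy pieces
# ---------------------------------------------------------------------------

def neo_hookean_energy_density(C: np.ndarray, c1: float) -> np.ndarray:
    """W = C1 (I1 - 3) with I1 = tr C; C must be symmetric positive-definite."""
    C = np.asarray(C, float)
    Cm = C.reshape(-1, 3, 3)
    if not np.allclose(Cm, np.transpose(Cm, (0, 2, 1)), atol=1e-8):
        raise WarpError("C must be symmetric")
    ev = np.linalg.eigvalsh(Cm)
    if np.any(ev <= 0):
        raise WarpError("C must be positive-definite")
    I1 = np.einsum("mkk->m", Cm)
    W = c1 * (I1 - 3.0)
    return W.reshape(C.shape[:-2]) if C.ndim > 2 else float(W[0])


def similarity_penalty(r, t, gamma: float):
    """U = gamma/2 (r - t)^2 — the pointwise image mismatch penalty."""
    d = np.asarray(r, float) - np.asarray(t, float)
    out = 0.5 * gamma * d * d
    return float(out) if np.isscalar(r) and np.isscalar(t) else out

# 4-point Gauss rule on the reference tetrahedron (degree 2)
_QA = 0.5854101966249685
_QB = 0.1381966011250105
QUAD_4 = (
    np.array(
        [
            [_QA, _QB, _QB, _QB],
            [_QB, _QA, _QB, _QB],
            [_QB, _QB, _QA, _QB],
            [_QB, _QB, _QB, _QA],
        ]
    ),
    np.full(4, 0.25),
)

# centroids of the 1:8 red refinement (equal sub-volumes): a denser
# sampling rule for the non-polynomial image term — the element size
# (several mm) far exceeds the voxel size, and with only 4 samples the
# optimizer can park features between sample points
QUAD_8 = (
    np.array(
        [
            [5, 1, 1, 1],
            [1, 5, 1, 1],
            [1, 1, 5, 1],
            [1, 1, 1, 5],
            [3, 2, 1, 2],
            [2, 3, 2, 1],
            [2, 1, 2, 3],
            [1, 2, 3, 2],
        ]
    )
    / 8.0,
    np.full(8, 0.125),
)

QUAD_RULES = {"gauss4": QUAD_4, "sub8": QUAD_8}
QUAD_BARY, QUAD_W = QUAD_4  # backwards-compatible module-level default


def template_intensities(
    mesh: BivMesh, series: ImageSeries, config: WarpConfig
) -> np.ndarray:
    """R: ES-frame intensities sampled once at the reference quadrature points."""
    B, w = QUAD_RULES[config.quadrature]
    Xq = np.einsum("qa,mak->mqk", B, mesh.cell_coords())
    vals, _ = sample_image(
        series, series.es_index, Xq.reshape(-1, 3), config.smoothing_sd
    )
    return vals.reshape(mesh.n_cells, len(w))


def warping_energy(
    mesh: BivMesh,
    u: np.ndarray,
    series: ImageSeries,
    target_frame: int,
    config: WarpConfig,
    template: np.ndarray | None = None,
):
    """Total energy E(u) and its gradient w.r.t. nodal displacements.

    Returns ``(E, grad, feasible)``; ``feasible`` is False when any
    element is inverted (J <= 0), in which case E is +inf and the
    gradient is meaningless (the line search uses this as a rejection
    flag).
    """
    u = np.asarray(u, float).reshape(mesh.n_nodes, 3)
    if not np.all(np.isfinite(u)):
        raise WarpError("displacement must be finite")
    if template is None:
        template = template_intensities(mesh, series, config)
    G = mesh.shape_gradients()
    V = mesh.cell_volumes()
    xc = (mesh.nodes + u)[mesh.cells]  # (m,4,3)

    F = np.einsum("mak,maj->mkj", xc, G)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        return np.inf, np.zeros((mesh.n_nodes, 3)), False

    # Neo-Hookean regularizer in decoupled (isochoric + volumetric)
    # form: W = C1 (J^{-2/3} I1 - 3) + kappa/2 (J - 1)^2.  Both parts
    # are nonnegative and stress-free at F = I, so perfectly matched
    # images yield exactly zero displacement; the isochoric part does
    # not penalize physiological volume change (systolic compression
    # would otherwise be resisted even where the images demand it),
    # while kappa keeps runaway local volume change in check.  (The
    # paper's plain I1 - 3 density is unbounded below under compression
    # and would reward element collapse when minimized.)
    I1 = np.einsum("mkj,mkj->m", F, F)
    Jm23 = J ** (-2.0 / 3.0)
    E_el = float(
        np.sum(
            (config.c1 * (Jm23 * I1 - 3.0) + 0.5 * config.kappa * (J - 1.0) ** 2) * V
        )
    )
    Finv_T = np.transpose(np.linalg.inv(F), (0, 2, 1))
    dW_dF = (
        2.0 * config.c1 * Jm23[:, None, None] * (F - (I1 / 3.0)[:, None, None] * Finv_T)
        + (config.kappa * (J - 1.0) * J)[:, None, None] * Finv_T
    )
    grad_cell = V[:, None, None] * np.einsum("mkj,maj->mak", dW_dF, G)  # (m,4,3)

    B, w = QUAD_RULES[config.quadrature]
    xq = np.einsum("qa,mak->mqk", B, xc)  # (m,q,3)
    tval, tgrad = sample_image(
        series, target_frame, xq.reshape(-1, 3), config.smoothing_sd
    )
    q = len(w)
    tval = tval.reshape(mesh.n_cells, q)
    tgrad = tgrad.reshape(mesh.n_cells, q, 3)
    diff = template - tval
    E_im = float(np.sum(0.5 * config.gamma * diff**2 * w[None, :] * V[:, None]))
    dE_dxq = (-config.gamma * diff * w[None, :] * V[:, None])[..., None] * tgrad
    grad_cell += np.einsum("qa,mqk->mak", B, dE_dxq)

    grad = np.zeros((mesh.n_nodes, 3))
    np.add.at(grad, mesh.cells.reshape(-1), grad_cell.reshape(-1, 3))
    return E_el + E_im, grad, True


# ---------------------------------------------------------------------------
# Basal boundary condition
# ---------------------------------------------------------------------------

def basal_displacement(
    frame: int, config: WarpConfig, series: ImageSeries
) -> float:
    """Prescribed longitudinal basal displacement (mm), ES-referenced.

    d(t) = mapse * (1 - phase(t)) along the apex->base axis: zero at ES
    (the tracking origin) and +mapse at ED, when the base sits farthest
    from the apex.  ``bc_profile`` selects the phase law (only the
    piecewise sin^2 law is provided).
    """
    if config.bc_profile != "sin2":
        raise WarpError(f"unknown bc_profile {config.bc_profile!r}")
    p = float(
        cycle_phase(frame, series.n_frames, series.es_index, series.ed_index)
    )
    return config.mapse * (1.0 - p)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

def _project_grad(g: np.ndarray, base_nodes: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Remove the longitudinal component of the gradient at basal nodes."""
    if base_nodes.size:
        gb = g[base_nodes]
        g = g.copy()
        g[base_nodes] = gb - np.outer(gb @ axis, axis)
    return g


def register_frame(
    mesh: BivMesh,
    u_init: np.ndarray,
    series: ImageSeries,
    target_frame: int,
    bc_value: float,
    config: WarpConfig,
    template: np.ndarray | None = None,
):
    """Minimize the warping energy for one target frame.

    The longitudinal component of every BASE-tagged node is held at
    ``bc_value`` (in-plane basal motion stays free); all other nodal
    displacements are optimized with projected L-BFGS + backtracking.
    Returns ``(u, log)`` with a monotone energy history in the log.
    """
    if template is None:
        template = template_intensities(mesh, series, config)
    axis = np.asarray(mesh.long_axis, float)
    base = mesh.surface_nodes(Surface.BASE)

    def fg(uu):
        E, g, ok = warping_energy(mesh, uu, series, target_frame, config, template)
        return E, _project_grad(g, base, axis), ok

    def apply_bc(uu, blend):
        """Warm start: spread the basal longitudinal change down the long
        axis (0 at apex, 1 at base) so it does not shear the basal
        element layer, then pin the base exactly."""
        uu = uu.copy()
        if base.size:
            proj = mesh.nodes @ axis
            ramp = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-30)
            delta = bc_value - float(np.mean(uu[base] @ axis))
            uu += (blend * delta * ramp)[:, None] * axis
            ub = uu[base]
            uu[base] = ub - np.outer(ub @ axis, axis) + bc_value * axis
        return uu

    u_prev = np.array(u_init, float).reshape(mesh.n_nodes, 3)
    proj = mesh.nodes @ axis
    ramp = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-30)
    candidates = [apply_bc(u_prev, b) for b in (1.0, 0.5, 0.0)]
    # last resort: forget the warm start, pure affine long-axis stretch
    candidates.append(bc_value * ramp[:, None] * axis)
    for u in candidates:
        E, g, ok = fg(u)
        if ok:
            break
    if not ok:
        raise WarpError("initial displacement inverts elements (J <= 0)")
    log = {"energies": [E], "n_feval": 1, "converged": False, "warning": None}

    mem_s, mem_y = [], []
    for it in range(config.max_iter):
        gflat = g.ravel()
        # standard two-loop recursion for the L-BFGS direction
        qv = gflat.copy()
        alphas = []
        for s, y in zip(reversed(mem_s), reversed(mem_y)):
            rho = 1.0 / (y @ s)
            a = rho * (s @ qv)
            qv -= a * y
            alphas.append((a, rho, s, y))
        if mem_y:
            y_last, s_last = mem_y[-1], mem_s[-1]
            qv *= (s_last @ y_last) / (y_last @ y_last)
        for a, rho, s, y in reversed(alphas):
            b = rho * (y @ qv)
            qv += (a - b) * s
        d = -qv
        if d @ gflat >= 0:  # not a descent direction; reset
            d = -gflat
            mem_s, mem_y = [], []
        dmat = _project_grad(d.reshape(-1, 3), base, axis)
        d = dmat.ravel()

        step = 1.0
        accepted = False
        gd = gflat @ d
        for _ in range(40):
            u_new = u + step * d.reshape(-1, 3)
            E_new, g_new, ok = fg(u_new)
            if ok and E_new <= E + 1e-4 * step * gd:
                accepted = True
                break
            step *= 0.5
        log["n_feval"] += 1
        if not accepted:
            log["warning"] = "line search failed; returning best feasible iterate"
            break

        s_vec = (u_new - u).ravel()
        y_vec = (g_new - g).ravel()
        if s_vec @ y_vec > 1e-12 * np.linalg.norm(s_vec) * np.linalg.norm(y_vec):
            mem_s.append(s_vec)
            mem_y.append(y_vec)
            if len(mem_s) > config.lbfgs_memory:
                mem_s.pop(0)
                mem_y.pop(0)

        u, g = u_new, g_new
        log["energies"].append(E_new)
        rel_drop = (E - E_new) / max(abs(E), 1e-30)
        E = E_new
        if rel_drop < config.tol or np.linalg.norm(g) < 1e-14:
            log["converged"] = True
            break
    log["n_iter"] = it + 1 if config.max_iter else 0
    return u, log


def track_cycle(mesh: BivMesh, series: ImageSeries, config: WarpConfig) -> MotionSolution:
    """Register the ES mesh to every frame of the cycle.

    Frames are visited in temporal order starting at ES and wrapping
    around the cycle, each warm-started from the previous solution; the
    template R stays the ES frame sampled on the undeformed mesh.  The
    displacement at the ES frame is exactly zero by construction.
    """
    mesh.check()
    T = series.n_frames
    es = series.es_index % T
    order = [(es + k) % T for k in range(T)]
    template = template_intensities(mesh, series, config)

    G = mesh.shape_gradients()
    u_all = np.zeros((T, mesh.n_nodes, 3))
    F_all = np.zeros((T, mesh.n_cells, 3, 3))
    energies = np.zeros(T)
    logs = [None] * T

    u = np.zeros((mesh.n_nodes, 3))
    for t in order:
        if t == es:
            u_t = np.zeros_like(u)
            log = {"energies": [], "skipped": "ES is the tracking origin"}
        else:
            bc = basal_displacement(t, config, series)
            u_t, log = register_frame(mesh, u, series, t, bc, config, template)
        F = np.einsum("mak,maj->mkj", (mesh.nodes + u_t)[mesh.cells], G)
        if np.any(np.linalg.det(F) <= 0):
            raise WarpError(
                f"frame {t}: accepted state inverts elements; aborting at last good frame"
            )
        u_all[t] = u_t
        F_all[t] = F
        energies[t] = log["energies"][-1] if log.get("energies") else 0.0
        logs[t] = log
        u = u_t
    return MotionSolution(
        mesh=mesh,
        u=u_all,
        F=F_all,
        energies=energies,
        iteration_log=logs,
        es_index=es,
        ed_index=series.ed_index % T,
        frame_times=np.asarray(series.frame_times, float),
    )
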