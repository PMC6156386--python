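# Methods

`cardiowarp` measures regional myocardial strain from cine short-axis
image stacks by hyperelastic warping: a finite-element (FE) model of
the biventricular unit, built at end-systole (ES), is deformed through
the frames of the cardiac cycle by image-derived forces, and the
tracked deformation gradients are converted into circumferential,
longitudinal and radial Green–Lagrange strain–time curves for the LV
free wall, septum and RV free wall.  This note records the model, its
assumptions, the numerical choices, and what the synthetic phantom
does and does not establish.

## Registration model

Per target frame the nodal displacement field `u` minimizes

    E(φ) = ∫ W(X, C) dV  +  ∫ (γ/2) (R(X) − T(φ(X)))² dV,

with `φ(X) = X + u(X)`, `F = ∂φ/∂X`, `C = FᵀF`, template `R` the ES
frame sampled once at the quadrature points of the undeformed mesh,
and `T` the target frame sampled at the mapped points.  The image
mismatch enters as a penalty with weight `γ`; the force it exerts on
the mesh is proportional to the intensity difference times the target
intensity gradient, exactly the driving force of hyperelastic warping.

The regularizer is a Neo-Hookean strain energy.  The classical
incompressible-form density `C1(I1 − 3)` (exposed as
`neo_hookean_energy_density`) is unbounded below under compression
(`I1 < 3`) and carries a nonzero stress at the undeformed state, so as
an energy to be *minimized* it rewards element collapse and makes
`u = 0` non-stationary even for perfectly matched images.  The
assembled energy therefore uses the standard decoupled
(isochoric + volumetric) form

    W = C1 (J^(−2/3) I1 − 3) + κ/2 (J − 1)²,

which is nonnegative, vanishes exactly on rigid motions, and is
stress-free at `F = I` — this is what makes the zero-force fixed point
(static images, zero boundary displacement ⇒ `u = 0`) exact rather
than approximate.  The split matters physically: a coupled density
(e.g. `I1 − 3 − 2 ln J`) penalizes the *volume change* of systolic
deformation itself, and measurably biases the registration against
longitudinal compression wherever the images cannot observe it; the
isochoric part is indifferent to volume change, and the small `κ` term
only suppresses runaway local volume drift.

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `gamma` | 0.005 | (intensity²)⁻¹-scaled | image mismatch penalty weight; fixed for all cases |
| `c1` | 1e-4 | per intensity² | isochoric Neo-Hookean modulus; see below |
| `kappa` | 1e-4 | per intensity² | volumetric modulus of the decoupled density |
| `mapse` | per subject | mm | basal longitudinal excursion amplitude |
| `smoothing_sd` | 1.5 | mm | Gaussian presmoothing of each frame before sampling |
| `tol` / `max_iter` | 1e-6 / 200 | — | per-frame convergence: relative energy decrease |
| `quadrature` | `sub8` | — | image-term sampling rule per tetrahedron |

`c1` and `γ` only matter through their ratio once intensities are
normalized to [0, 1].  The default `c1 = 1e-4` was chosen so that the
elastic cost of a physiological deformation (strains of 10–20%) stays
an order of magnitude below the image-mismatch signal of a misaligned
wall, while displacement wiggles at the image-noise scale remain
penalized; raising `c1` ten-fold visibly suppresses wall thickening
(the most volume-active strain component), and lowering it ten-fold
admits spurious in-plane deformation.

### Boundary condition

Short-axis stacks carry almost no through-plane information, so the
basal longitudinal motion is prescribed: every BASE-tagged node has
the longitudinal component of its displacement fixed to

    d(t) = MAPSE · (1 − phase(t)),

with `phase` a piecewise sin² law equal to 0 at ED and 1 at ES (it
reduces to sin²(π t/T) when ES sits at mid-cycle).  Displacements are
ES-referenced, so `d(ES) = 0` and `|d(ED)| = MAPSE`: the base sits
farthest from the apex at end-diastole.  In-plane motion of basal
nodes stays free.  Only the longitudinal component is constrained, and
the optimizer works in the corresponding affine subspace (gradient and
search direction are orthogonally projected).

### Optimizer

Projected L-BFGS (memory 8) with Armijo backtracking.  Any trial step
that inverts an element (J ≤ 0 on any cell) is rejected by the line
search, so every accepted iterate is feasible and the per-frame energy
sequence is non-increasing.  Frames are visited in temporal order
starting at ES and wrapping around the cycle, warm-started from the
previous frame; the change in the basal boundary value between frames
is spread linearly down the long axis before optimization (a pure
basal jump would shear the basal element layer and could invert thin
elements).  Convergence is declared at a relative energy decrease
below `tol` or at the iteration cap.

### Image sampling

Intensity is evaluated by trilinear interpolation of the (optionally
Gaussian-presmoothed) volume.  The spatial gradient is the *exact*
analytic gradient of the trilinear interpolant, not an interpolated
central-difference stencil: the assembled energy gradient then matches
central finite differences at machine-level accuracy, which both the
test suite and the optimizer's line search rely on.  Points outside
the grid return intensity 0 with zero gradient.

The image term is integrated with the `sub8` rule (centroids of the
1:8 red refinement of each tetrahedron, equal weights).  Elements are
several millimetres across while voxels are ~1.5 mm, so a 4-point rule
undersamples the mismatch field enough that the optimizer can park
intensity features between sample points; 8 points per element remove
most of that artifact at twice the cost.  The elastic term needs only
one point per element (P1 elements, constant F).

## Strain post-processing

Tracking is ES-referenced but strain is reported against ED.  With
`F` and `F_ED` the tracked gradients of a cell, the relative gradient
`F_rel = F F_ED⁻¹` re-references the motion, and

    E = ½ (F_relᵀ F_rel − I)

is the Green–Lagrange strain with ED as reference — exactly zero at ED
for every cell, rigid-motion insensitive, and equal to
ΔL/L + ½(ΔL/L)² in one dimension.  Normal components are
`ε_ii = e_i · E e_i` along the per-cell triads.  Region curves are
unweighted means over the elements of each region (a volume-weighted
option exists behind a flag); peak systolic values are the extrema
over the ED→ES arc — minimum for ε_CC and ε_LL, maximum for ε_RR —
reported in percent with sign kept.  A whole-cycle peak window is
available for data with strong atrial-kick effects.

## Direction triads

Laplace–Dirichlet rule-based construction with myofiber angle fixed at
zero, per element.  Harmonic coordinates are solved with P1 elements
(direct sparse factorization):

* transmural, LV side: LV_ENDO = 0, RV_ENDO = EPI = 1 — used for LV
  free wall and septum, so the septal radial vector points LV → RV;
* transmural, RV side: RV_ENDO = 0, LV_ENDO = EPI = 1 — used for the
  RV free wall;
* apicobasal: BASE = 1 and a point-region apex patch (lowest 2% of
  nodes along the long axis) = 0 — no apex facet tag exists, and a
  point patch is the standard workaround.

A single combined transmural solve (both endocardia at 0) is *not*
usable: such a field peaks inside the septum and its gradient vanishes
there, so no septal radial direction could be oriented.  Per-cell
gradients are recovered by volume-weighted nodal averaging (one
scatter/gather pass): the raw P1 gradient is constant per cell and
vanishes identically on "flat" cells whose four vertices all lie on
one Dirichlet surface — unavoidable where a thin wall is one element
thick.  Residual zero-gradient patches (crescent horns) are
flood-filled from resolved neighbours.  `e_R` is the normalized
transmural gradient (outward; LV→RV in the septum), `e_L` the
apicobasal gradient orthogonalized against `e_R` and oriented
apex→base, `e_C = e_L × e_R`; the triad is orthonormal and
right-handed on every cell, and on an idealized cylinder shell it
matches the analytic cylindrical frame to better than 2°.

## Region partition

Two harmonic "distance-like" fields: `d_LV` (LV_ENDO = 0, EPI = 1) and
`d_RV` (RV_ENDO = 0, EPI = 1), natural conditions elsewhere.  The
septum is bounded by the two endocardia and far from the epicardium,
so both fields stay small there; each free wall pins the *opposite*
field near 1 through the epicardium.  A cell is SEPTUM when both
centroid values are ≤ 0.5 (ties septal, for determinism); otherwise it
joins the free wall of the nearer endocardium.  The partition is
exhaustive, exclusive, deterministic, and stable under node
renumbering and rigid transforms.  Note that clamping *both*
endocardia in *both* fields would make the fields complementary
(`d_LV + d_RV ≈ 1` across the septum) and the septum empty — the
one-endocardium-per-field form is the workable reading of the
between-the-blood-pools rule.

## Synthetic phantom

No clinical data ship with the package; the phantom supplies a fully
controlled stand-in with an exact strain oracle.

**Geometry.**  LV: truncated thick-walled prolate ellipsoid (endo
semi-axes 25/25/50 mm, wall 9 mm).  RV: a thinner shell (outer
40/34/46 mm, wall 5 mm) offset 8 mm laterally and clipped against the
LV epicardium, so the RV cavity is the crescent between its inner
surface and the LV epicardial surface; the flat basal plane truncates
both at z = 15 mm.  This is the simplest solid with the
LV / septum / RV topology.  The modest offset keeps the RV wall frame
reasonably aligned with the cylindrical frame of the motion below, so
all three regions show physiological strain signs.

**Motion.**  Identity at ED, peak at ES, piecewise-sin² phase.  Three
commuting pieces, each with closed-form Jacobian (composed by the
chain rule) and closed-form inverse (used for rendering):

1. longitudinal: uniform stretch about the apex,
   `λ(p) = 1 − p · MAPSE / L` — the base moves toward the apex by
   MAPSE at ES;
2. in-plane: area-preserving radial map `ρ'² = ρ² − p δ²(z)`, with
   `δ²` proportional to the squared local LV endocardial radius
   (C²-smoothed to zero below the endocardial apex so the map stays
   real on the axis).  One drive produces circumferential shortening
   *and* transmural thickening simultaneously, as in systole; δ is
   calibrated so the LV equatorial endocardium shortens by the
   requested fraction (default 15%) at ES, plus a separate
   `thickening_amplitude` increment (default 0.05) that strictly
   thickens the wall;
3. optional twist about the long axis (default 0°: a rotationally
   near-symmetric bright wall gives intensity-based registration no
   tangential information — the aperture problem — so twist is left
   out of the default study conditions).

det F = λ(p) exactly; with `mapse = 0` the motion is perfectly
isochoric, which the volume-conservation rendering test exploits.

**Images.**  96×96×16 voxels at 1.5×1.5×8 mm (clinical short-axis
anisotropy), 30 frames/cycle, ES at frame 15.  Wall voxels are bright
(1.0) on dark (0.0) background; partial volume from 2× supersampling
per axis through the exact inverse motion; seeded Gaussian noise
(default sd 0.05) added per frame, then clipped to [0, 1].  Everything
is reproducible bit-for-bit from the PhantomSpec (a single seed drives mesh
jitter and noise).

**Meshing.**  BCC lattice interior points plus implicit-surface
projected boundary points, Delaunay-tetrahedralized; cells outside the
solid are discarded, boundary pinches and flat slivers stripped, and
vertex positions relaxed (Laplacian passes with boundary re-projection,
then local optimization around the worst cells).  The sliver repair is
not cosmetic: a near-degenerate element inverts under interpolated
physiological deformations and would block the feasibility-preserving
line search.  At the default characteristic length (5.8 mm) the mesh
carries ~2.6k nodes and ~9.5k cells — the scale used for clinical
biventricular models.  Boundary facets are tagged by probing which
region lies just beyond them; the region partition runs the same
Laplace rule as for imported meshes.

**Oracle.**  The exact deformation gradient at each ED cell centroid
is pushed through the *same* remap → project → region-average code
path as the tracked solution, with triads and labels from the ES
configuration (as in the clinical pipeline).  For affine motions this
reproduces closed forms ((λ²−1)/2, −s+s²/2) to 1e-10, which pins the
shared path itself.

**What the phantom does not emulate.**  Receive-coil intensity bias,
trabeculation and papillary muscles, through-plane flow artifacts,
breathing/misregistration between slices, a moving ED reference
(images are resampled consistently from one continuum motion), and
twist.  Passing the recovery test therefore shows the pipeline can
invert its own forward model under clinical voxel anisotropy and
noise — not that clinical accuracy equals phantom accuracy.

## Statistics layer

* Bland–Altman: bias, SD of paired differences, limits bias ± 1.96 SD.
* CV%: SD of paired differences over the mean absolute pair mean —
  scale-invariant and symmetric in the raters (other conventions
  exist; this one is documented and configurable by computing from the
  returned pieces).
* ICC(2,1): two-way random effects, absolute agreement, single
  measurement, from the mean-squares decomposition, with the standard
  F-distribution confidence bounds; the conventional form for
  observer-reproducibility of strain.
* ROC: empirical, on strain magnitudes with "smaller magnitude =
  diseased" polarity, so cutoffs for negative-valued strains are
  positive numbers; AUC by the Mann–Whitney construction (identical to
  the trapezoid over the empirical curve); cutoff maximizes Youden's
  J, ties resolved toward the lower cutoff.
* Group comparison: Shapiro–Wilk gate at 0.05 between t-test and
  Mann–Whitney U; Fisher's exact test for 2×2 categorical tables.

## Numerical choices and degenerate inputs

* P1 tetrahedra throughout; one deformation gradient per element.
* Laplace solves: direct sparse Cholesky-like factorization
  (`spsolve`); Dirichlet rows eliminated.
* Strain at ED is exactly zero by construction (remap), not within a
  tolerance.
* Meshes with inverted cells are auto-reoriented on import; a missing
  surface tag is reported by name; an empty region is an error.
* Degenerate statistics inputs (n < 2 pairs, single-class ROC, zero
  variance ICC) raise typed errors rather than returning NaN.
* The demo pipeline and acceptance script downscale the phantom
  (fewer frames / coarser grids) where a check does not need the full
  default resolution; the full 96×96×16 / 30-frame setting is used for
  the parameter-recovery check itself.

## Known limitations

* Longitudinal information away from the basal boundary condition and
  the apex cap is intrinsically weak in 8 mm-slice short-axis stacks.
  On the noise-free default phantom the energy's minimizer itself —
  not the optimizer — deviates from the true motion in the
  through-plane-dominated components: starting the solver *at* the
  exact ground-truth displacement, it leaves it for a lower-energy
  state, and the recovered septal/RV ε_LL and LV/RV ε_RR peaks are off
  by 2.5–3.8 strain points while all ε_CC components, LV ε_LL and
  septal ε_RR land within a fraction of a point.  The longitudinal
  profile is bistable under the regularization weights (it either
  rides with the base or over-compresses), so no weight setting
  removes the bias.  This is the registration-side face of the known
  out-of-plane-resolution limitation that motivates prescribing the
  basal excursion in the first place; the recovery report in the
  acceptance output quantifies it per component.
* The RV free wall is one element thick at default mesh density, so
  its strain averages rest on fewer, lower-quality elements than the
  LV's.
* Only fixed γ is supported; γ-optimization is out of scope.
* No multi-resolution image pyramid and no GPU path; runtimes are
  minutes per cycle at default resolution on one core.
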