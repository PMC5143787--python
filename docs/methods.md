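# Methods

## Forward model

Light transport at the excitation (`x`) and emission (`m`) wavelengths is
modelled by the diffusion approximation on a 2D rectangular domain:

    -div(D_x grad Phi_x) + mu_ax Phi_x = Theta * delta(r - r_s)
    -div(D_m grad Phi_m) + mu_am Phi_m = Phi_x * x

with `D = 1/(3 (mu_a + mu_s'))` (mm), `mu_a` the absorption and `mu_s'` the
reduced scattering coefficient (mm^-1), and the Robin boundary condition
`Phi + 2 kappa D dPhi/dn = 0` (`kappa = 1` by default, index-matched
boundary).  `x` is the nodal fluorescent yield to be reconstructed.

The equations are discretised with a node-centred finite-volume scheme on a
uniform grid (5-point stencil; boundary nodes own half cells, corners quarter
cells; the Robin term contributes `facelen/(2 kappa)` to the diagonal).  The
resulting operator is a symmetric positive-definite M-matrix, which gives two
properties the tests rely on: strictly positive fields for nonnegative
nonzero sources (discrete maximum principle), and exact source-detector
reciprocity through operator symmetry.

Point sources deposit their full mass `Theta` on the nearest grid node
(equivalently, a nodal source density `Theta/h^2` over a nominal cell
`h^2`); distributed emission sources use the same uniform `h^2` cell weight.
With these conventions the Born sensitivity row

    A[(s,d), j] = Phi_x^s(r_j) * G_m^d(r_j) * h^2,

with `G_m^d` the emission-wavelength adjoint field of a unit source at
detector `d`, agrees with the brute-force alternative (unit yield at node
`j`, emission solve, detector read-out) to machine precision, which the test
suite verifies column by column.

A 2D structured grid replaces the unstructured 3D meshes of practical FMT:
it preserves everything the solver sees — an elliptic, severely ill-posed
linear system with `M < N` and correlated rows — at desk scale, and the
solver stack is discretisation-agnostic since it only consumes `A`.

## Preconditioner

`W = (S S^T + lambda I_M)^(-1/2) U^T` from the SVD `A = U S V^T`.  With
`lambda = 0` and full row rank, `B = W A` has exactly orthonormal rows
(`B B^T = I_M`), so one sequential Kaczmarz sweep solves a consistent system.
Singular values below `rank_tol * sigma_max` are treated as exactly zero with
their reciprocals set to zero (pseudo-inverse convention); the default
`rank_tol = max(M, N) * eps` is the conventional numerical-rank rule.

Two numerical observations shape the API:

- **Diagonal loading is inert in a row-action solver.**  A Kaczmarz
  projection onto `B_i x = y_i` is invariant to any rescaling of the row, and
  loading rescales rows (`B_i -> sigma_i/sqrt(sigma_i^2+lambda) v_i^T`)
  without moving the hyperplane `v_i^T x = u_i^T phi / sigma_i`.  Loading
  therefore regularises only through the rows it (together with `rank_tol`)
  effectively removes.  The `loading` parameter is kept for fidelity to the
  algorithm's published form (`"auto"` = `1e-6 sigma_max^2`), but noisy data
  should be handled by spectral truncation.
- **Noise-adapted truncation.**  `noise_adapted_rank_tol` picks the smallest
  rank whose truncated solution fits the data to within the noise
  (`||phi - A x_r|| <= sqrt(M) sigma`, the Morozov discrepancy principle).
  Directions beyond that rank carry spectral coefficients at or below the
  noise floor; projecting onto their hyperplanes amplifies noise by
  `1/sigma_i` without adding information.

`W` and `B` are formed densely; at desk scale (`M` in the hundreds) both fit
comfortably in memory and the SVD is computed once, before iteration.

## Solver

One "iteration" is one full sequential sweep over all `M` rows followed by
one thresholding step; this matches how sweep counts are usually reported
for ART-type methods.  Rows whose norm falls below `1e-14` of the largest
row norm are skipped (numerically zero rows, e.g. truncated directions).
The iterate starts at zero, and iteration stops at the sweep cap `K_iter` or
when `||x^k - x^(k-1)||_2 < eps` (`eps = 1e-6` by default; the examples use
`0` to run a fixed budget).  No relaxation parameter is used.

The threshold level is re-derived every iteration.  `find_beta` minimises
`|sparsity(threshold(x, beta)) - psi|` over the exact discrete candidate set:
the distinct positive entries of `x`, each defining the support "all entries
at or above this value".  A support that would split a group of tied values
is unreachable by any single threshold and is excluded.  Candidate
sparsities are evaluated with cumulative-norm identities (O(P log P) total);
ties in the objective break toward the sparser result (larger `beta`).  The
thresholded vector is computed with the exact cutoff value rather than
`beta * max(x)` so that a one-ulp rounding in the division cannot drop a
tied boundary entry.  Thresholding compares signed values, so with a
positive maximum every negative entry is zeroed — the constraint doubles as
a nonnegativity projection.  If an iterate has no positive entry at all, the
solver warns and returns the zero vector for that step instead of failing.

The Hoyer measure is implemented in its square-root form
`(sqrt(N) - ||x||_1/||x||_2)/(sqrt(N) - 1)`: this is the form whose range is
[0, 1] and whose values for 1/10/30-of-300 indicator vectors are 1, 0.87 and
0.73, the reference curve the implementation is checked against.

`wanted_sparsity_from_fraction(f, N)` maps an estimated target-to-domain
volume fraction to `psi = (sqrt(N) - sqrt(round(f N)))/(sqrt(N) - 1)`
(at least one node), assuming a uniform target.

With preconditioning disabled (`W = I`) and the constraint off, the driver
reduces bit-for-bit to the classical Kaczmarz baseline, which is also
exposed directly (`classical_kaczmarz`); from `x0 = 0` on a consistent
system it converges to the minimum-norm solution.

## Metrics

- Relative deviation `delta = ||x_r - x_t||_2 / ||x_t||_2` — the primary
  accuracy score.
- `dice_coefficient`: the intensity-weighted form
  `2 ||x_r o x_t||_2 / (||x_r||_2^2 ||x_t||_2^2)` as conventionally reported
  for this problem.  Note it is not bounded by 1 (two coincident unit
  impulses score 2) and scales inversely with amplitude; it is reported for
  fidelity.
- `support_dice`: the conventional bounded overlap
  `2 |S_r ∩ S_t| / (|S_r| + |S_t|)` on supports delineated at half maximum
  (FWHM convention; `rel_threshold` adjustable).  Recovery claims are judged
  on this score.
- `localization_error`: Euclidean distance between the intensity-weighted
  centres of mass (negative entries carry no weight), in mm.

## Synthetic data

`make_scenario` defaults: 20 mm x 20 mm domain on a 32 x 32 grid (spacing
20/31 mm, N = 1024), homogeneous muscle optics
(`mu_ax = 0.0052, mu_sx' = 1.08, mu_am = 0.0068, mu_sm' = 1.03` mm^-1 from
the standard small-animal organ table bundled as `ORGAN_PROPERTIES`), five
point sources placed one transport mean free path `1/mu_sx'` (~0.93 mm)
beneath the surface, equally spaced along the inset perimeter and snapped to
grid nodes, and detectors on every boundary node (124), giving
M = 620 < N = 1024.  Preset layouts: one 1.5 mm disk at (12.9, 9.9) mm;
two 1 mm disks at (13, 12) and (13, 6) mm; three 1 mm disks at (11, 10),
(14, 14) and (13, 6) mm.  Spheres of the 3D setting become disks; radii and
intensities keep their meaning.

Measurement noise is additive zero-mean Gaussian with standard deviation
`noise_level * mean(|A x_true|)` (1% by default), seeded and reproducible;
with a zero signal the noise scale is zero by construction.  Bundles are
fully determined by (config, seed) and serialise exactly through the
MatrixMarket/CSV writers.

`make_random_system` supplies abstract fixtures with controlled
singular-value decay ("flat" = orthonormal-spectrum rows, "geometric" =
`decay**i`) and a sparse nonnegative ground truth, for solver tests
independent of the optics.

What the generator does *not* emulate: model mismatch (data are produced by
the same diffusion model used for inversion — the inverse-crime setting),
heterogeneous optical property maps, free-space propagation and camera
physics, and shot-noise statistics.  Passing tests therefore demonstrate the
algebraic claims (orthogonalisation, one-sweep convergence, sparsity
control, recovery under consistent data), not performance on real
measurements.

## Noise and attainable accuracy

On the default two-target scenario the singular spectrum of `A` decays
roughly geometrically (about one decade per ~70 modes).  With 1% relative
noise, only the first ~200 of 620 spectral directions carry signal above the
noise floor, and less than half of the ground truth's energy lies in the
corresponding right-singular subspace.  No estimator consistent with such
data can reach a small relative deviation; empirically the constrained
solver localises the targets (support overlap high) but plateaus at
`delta ~ 0.5-0.7`, whereas with exact data it reaches `delta < 0.2` within
ten sweeps (see `tests/test_recovery.py` and the noisy-recovery acceptance
test, which records this gap).  Users should treat `delta` targets below ~0.5
as requiring sub-0.1% measurement noise at this problem size.

## Problem sizes

Default test and example sizes — 32 x 32 grids (N = 1024, M = 620), random
systems up to 100 x 400, sweep budgets of 100 (constrained) to 3000
(baseline convergence checks) — were chosen so the full suite runs in well
under a minute on one core while still exhibiting the ill-conditioning the
method targets.

## Known limitations

- 2D only; no unstructured meshes or heterogeneous property maps.
- Dense SVD preconditioning scales as O(M^2 N); fine for desk scale, not for
  `N` in the 10^5 range.
- Sequential row access only; randomised or greedy access orders and block
  updates are out of scope.
- The printed intensity-weighted Dice is reported as defined even though it
  is unbounded; use `support_dice` for a calibrated overlap score.
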