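# Methods

This note documents the model, the discretization, the design decisions taken
where the formulation was genuinely open, and the limits of what the synthetic
experiments demonstrate.

## Variational model

Registration minimizes

```
E(v) = 1/2 <L v, v> + 1/sigma^2 E_img(m(1), I1),
```

over a stationary velocity field `v` on the periodic unit domain `[0,1)^d`,
`d = 2, 3`.  `L = (Id − alpha Δ)^s` is the Sobolev metric operator with inverse
`K`; both are applied through the exact spectral symbol
`(1 + alpha |2 pi k|^2)^s`, so `K L = Id` holds to machine precision and both
operators are exactly self-adjoint under the discrete unit-domain inner
product `<f, g> = mean(f g)`.

Defaults `sigma^2 = 1.0`, `alpha = 0.0025`, `s = 2` are the standard operating
point for unit-domain brain registration with this family of methods; `s = 2`
keeps velocities in a space embedded in C^1 (diffeomorphic flows), and `alpha`
trades smoothness against recovery accuracy.  With SSD on `[0,1]`-scaled
images this operating point deliberately under-fits: the converged relative
intensity error (MSErel) on the default synthetic pair is 8–12% depending on
the realization, while NCC — whose image term is larger relative to the
regularizer — reaches 1–3%.

The warped image is always the composition `m(1) = I0 ∘ phi(1)` where the
pullback map `phi` solves `d(phi)/dt + D(phi) v = 0`, `phi(0) = id`.  The
inverse map `psi` solves the time-reversed equation anchored at `psi(1) = id`.
Note an easily-missed property of this pair: `psi(t)` is *not* the pointwise
inverse of `phi(t)` for intermediate `t` (checked in closed form for constant
`v`); it is the flow of `+v` over duration `1 − t`, which is exactly the
composition map the adjoint identity below requires.  At the endpoints,
`phi(1)` and `psi(0)` are mutual inverses — the acceptance suite checks
`‖phi(1) ∘ psi(0) − id‖ ≤ 0.1` voxel.

## Adjoint routes (Variants I and II)

Changing the similarity metric changes only two objects: the initial adjoint
`lambda(1) = −dE_img/dm(1)` and the Gauss–Newton incremental-adjoint operator
`dm(1) ↦ dlambda(1)`.  Two numerically distinct assemblies of the same
continuum gradient are implemented:

* **Variant I** — adjoint by change of variables:
  `lambda(t) = J(t) · lambda(1) ∘ psi(t)` with `J(t) = det D(psi(t))` from the
  inverse Jacobian equation `dJ/dt + v·∇J = −J ∇·v`, `J(1) = 1` (the sign of
  the right-hand side is fixed by requiring `J = det D(psi)`, which both the
  identity and the evaluation metrics rely on; the alternative sign propagates
  `1/det`).  The gradient accumulates `∫ lambda(t) ∇m(t) dt` with
  Clenshaw–Curtis quadrature on the CGL nodes — the natural quadrature for
  that node family.
* **Variant II** — vector adjoint of the deformation state equation:
  `rho(1) = lambda(1) · (∇I0) ∘ phi(1)`, transported backward by the
  continuity equation, gradient `Lv + ∫ Dphi(t)^T rho(t) dt` with the
  trapezoid pairing induced by the transpose of the discrete forward solve.
  The final condition is the stationarity condition of the Lagrangian with
  respect to `phi(1)` given `m(1) = I0 ∘ phi(1)`; a form with `∇m(1)` in
  place of `(∇I0) ∘ phi(1)` (differing by `Dphi(1)^T`) fails the
  directional-derivative oracle and was rejected.

Both routes satisfy `<∇E, w> = dE(v + eps w)/d(eps)` to ≤ 1e−3 relative
(measured ≈ 4e−4 worst case over all 20 metric × variant × parameterization
configurations, error scaled by `max(|dE/dw|, ‖∇E‖‖w‖)`); the two routes agree
with each other to a few parts in 10^3 on smooth problems, degrading with
deformation amplitude and image roughness — they are O(Δt²)-different
discretizations of the same object.

## Gauss–Newton operators

The Hessian-vector product is assembled as `L dv + Jᵀ H_img J dv` where `J` is
the linearized forward map `dv ↦ dm(1)` (incremental state equation in
Variant I, incremental deformation equation in Variant II) and
`−H_img = gn_operator` is the metric's PSD Gauss–Newton approximation.  The
backward pass is the **exact matrix transpose** of the discrete forward chain
(B-spline scatter + self-adjoint prefilter, trapezoid source pairing), so the
column-assembled Hessian is symmetric to machine precision, PSD by
construction, and matches a dense `Jᵀ H_img J + L` assembly exactly — the
acceptance suite verifies this on an 8² band-limited problem at 1e−6.

Per metric:

* **SSD**: `dlambda(1) = −(2/sigma^2) dm(1)` (exact Hessian).
* **NCC**: the full second differential of the correlation objective is
  indefinite away from the optimum (its quadratic form is negative for weakly
  correlated images), so the operator used is the Gauss–Newton `JᵀJ` of the
  orthogonality residual `r = m̄/√B − rho·Ī/√C` with `1 − rho² = ‖r‖²`.  It is
  PSD everywhere and coincides with the exact Hessian at zero residual
  (verified analytically and by a finite-difference oracle).
* **lNCC**: same residual construction per box window,
  `r(x,y) = (m(y) − mu_m(x))/√B(x) − rho(x)(I(y) − mu_i(x))/√C(x)` with
  `1 − rho(x)² = mean_y r(x,y)²`; the `JᵀJ` action is assembled entirely with
  box filters (no explicit window loops) and was validated against a
  brute-force windowed-residual oracle (7e−8), exact symmetry, and the true
  Hessian action near zero residual (0.6%).  A simpler `(d rho)(d rho)ᵀ`
  surrogate was tried first and rejected: it vanishes at zero residual, and
  gradient descent outperformed Gauss–Newton with it.
* **NGF**: `dlambda(1) = −(2/sigma^2) Jᵀ J dm` with `J dm = p · ∇dm`,
  `p = (∇I − (A/B²)∇m)/(BC)`; the second-order path uses matched
  central-difference gradient/divergence stencils (exact mutual adjoints under
  periodic wrap), the value/first-order path uses the spectral operators.
  Image gradients for NGF are taken in voxel units so that the default
  `eps² = 1000` has its conventional scale for `[0, 255]` intensities.
* **MI**: no second-order operator — the incremental adjoint couples every
  voxel pair through the joint histogram and is intractably dense.  MI is
  gradient-descent only, and requesting Gauss–Newton raises a configuration
  error.

## Transport discretization

All PDEs are solved semi-Lagrangianly at Chebyshev–Gauss–Lobatto nodes
`t_j = (1 − cos(pi j/N))/2`, `N = 5` by default.  Departure points use an
explicit midpoint (RK2) solve with 2 substeps per CGL interval; field values
are interpolated with a periodic cubic B-spline with prefiltering (exact on
degree-3 polynomials, 4th-order on smooth fields).  Sources are integrated
with the trapezoid rule along characteristics.  Measured against 100-substep
RK4 characteristics on a smooth analytic velocity (~5 voxels maximum
displacement at 64²), the state, deformation (both directions) and Jacobian
solves are accurate to ≤ 5e−4 sup-norm.

The continuity (adjoint) equation is solved as the exact discrete adjoint of
the advection step — scatter with the same B-spline weights, then the
self-adjoint prefilter.  Since the continuity equation is the formal adjoint
of advection, this is a consistent discretization; it conserves `∫ q` exactly
(to round-off) and is what makes the Gauss–Newton assembly exactly symmetric.
It cross-checks against the change-of-variables identity to ~2e−3 sup-norm
and reduces to backward advection exactly for divergence-free velocities.

The Jacobian equation is solved in advective form with an integrating factor
`exp(Δt ∇·v)` evaluated at the characteristic midpoint.

## Band-limited parameterization

Band-limited velocities store a centered box of Fourier-series coefficients
over the symmetric frequency set `|k_j| ≤ bounds_j // 2` (an odd number of
modes per axis, clipped to the grid).  The symmetric box is closed under
conjugate reflection, so Hermitian symmetry is enforced exactly at
construction, every lift `iota` is exactly real, `pi ∘ iota = id` exactly, and
`pi` is the exact adjoint of `iota` under the chosen inner products (plain l2
on coefficients, unit-domain mean in space).  When the box touches the grid
Nyquist frequency the single grid coefficient is split between the `±N/2`
modes, which makes the full-band case an exact isomorphism.

The truncated convolution `a ★ b = pi(iota(a) · iota(b))` is computed on a
zero-padded grid large enough to hold all product frequencies (alias-free),
and the genuinely band-limited deformation state equation
`du~/dt + (Du~) ★ v~ = v~` is integrated in coefficient space with RK4
(`solve_deformation_bl`).

The optimization pipeline, however, runs transport on the lifted velocity
`iota(v~)` with the spatial solvers and projects gradients and Hessian
products back with `pi`.  With a full band this reduces *exactly* (to
round-off) to the spatial formulation — a property the acceptance suite
checks at 1e−6 and that a band-native time integrator could not satisfy,
since it would discretize the flow differently.  For sub-bands this choice
spends more per-iteration work than a fully band-limited integrator but keeps
one transport code path and exact spatial/band consistency.

## Optimization

* Gradient descent: `v ← v − eps K ∇E` (Sobolev gradient), Armijo
  backtracking (`c = 1e−4`, halving, ≤ 10 trials), accepted step re-used and
  allowed to grow by one halving step per iteration; 50 outer iterations by
  default.
* Gauss–Newton–Krylov: PCG on `H dv = −∇E` with preconditioner `K`, at most
  5 inner iterations, forcing tolerance `min(0.5, sqrt(‖g_n‖/‖g_0‖))`;
  non-positive curvature aborts PCG with the current iterate, and a
  non-descent result falls back to `−K ∇E`; 10 outer iterations by default.
* Stopping: relative gradient `‖g_n‖∞/‖g_0‖∞ ≤ 1e−2`, or relative energy
  change ≤ 1e−4 over two consecutive iterations, or the iteration budget, or
  line-search stagnation.  The tolerances are design choices consistent with
  the relative-gradient levels at which this method family is considered
  converged.
* Multi-resolution: `levels` grids subsampled by factors `2^(levels−1) … 1`
  with periodic Gaussian anti-aliasing (`sigma = factor/2` voxels), the same
  iteration budget per level, and velocity transfer by exact Fourier
  embedding (band-limited: coefficient-box re-embedding).  On smooth
  small-displacement pairs single-resolution is already sufficient; the
  pyramid pays off on large displacements (~15 voxels) with structured
  templates, where the single-resolution solve stalls in a local minimum.

## Mutual information details

Intensities are mapped affinely from the declared range (default `[0, 255]`)
into bin coordinates `[2, bins − 3]` so the 4-tap cubic Parzen window's
support never leaves the histogram: the partition of unity, `sum p = 1`, and
exact marginal consistency then hold by construction.  The joint density and
the initial adjoint follow from the analytic window expression; entropy terms
use `0 log 0 = 0`.

Two consequences worth knowing:

* The estimator is smoothed: for identical images, `MI(I, I) = H(I) − H(s|r)`
  where the conditional-entropy bias is bounded by the log of the window
  support (≤ ln 7) and would vanish only for ideal delta histograms.  Tests
  therefore check the identity up to that analytically bounded bias, and the
  independence limit `MI ≈ 0` up to the Parzen bias of the sample size.
* The bin-coordinate map clamps at the range bounds, so the objective is only
  one-sided differentiable for voxels exactly at the extremes; the adjoint
  oracle tests use images valued strictly inside the range (where agreement is
  ~5e−9).

## Synthetic ground truth

`pdereg.synth` generates labeled templates (`blob`, `concentric_rings`,
`checker_organ`, each with ≥ 4 structures of varying scale), a random
band-limited velocity scaled to a target maximum displacement (default 6
voxels on 64², validated to keep `min J > 0`, amplitude reduced and resampled
otherwise), the warped pair via a fine integration of the ground-truth flow
(8 CGL steps, 4 substeps), optional monotone intensity remapping (`gamma`,
`inverted`, `quantile_remap`) to emulate a second modality, and optional
Gaussian noise (default none).  Everything is a deterministic function of the
seed.

What passing on this ground truth does and does not show: the fixtures are
smooth, periodic, noise-controlled and exactly self-consistent, so they
validate the *mathematics* — adjoint correctness, diffeomorphy, solver
fidelity, optimizer behavior.  They do not probe intensity inhomogeneity,
partial-volume effects, anatomy-scale feature statistics, non-periodic
boundaries, or inter-subject variability; accuracy numbers measured here do
not transfer to real brain MRI.

## Numerical choices and degenerate inputs

* Coordinates: voxel centers at `i/N`, 0-based, axes in array order; periodic
  boundaries everywhere (images are presmoothed — default Gaussian sd 1
  voxel — which also keeps the spectral differentiations well-behaved).
* Denominator floors: NCC rejects (near-)constant images; lNCC floors the
  windowed variances at `1e−10` of their maxima so flat patches stay defined.
* Parzen densities reject constant images (single occupied intensity).
* `interp`/`scatter` pairs share one B-spline weight computation, so
  gather/scatter adjointness is exact.
* Problem sizes in the test and acceptance suites (64² pipelines, 8²–32²
  operator assemblies, 5 CGL steps) were chosen as the smallest sizes at
  which the differential-geometry properties are cleanly measurable; all
  suites run in a couple of minutes on one core.

## Known limitations

* Stationary velocities only; a time-varying parameterization would need
  per-interval velocity storage but no structural change to the adjoints.
* Periodic boundary conditions are baked into the spectral operators; images
  whose content touches the boundary must be padded/smoothed by the caller.
* The lNCC window is an axis-aligned box (separable moving sums), not a
  Gaussian.
* MI is gradient-descent only (see above), and its Parzen smoothing biases
  both the value and, mildly, the location of the optimum.
* Variant I's identity-path adjoint and Variant II's transpose-chain adjoint
  are not bit-identical; mixing routes across restarts changes energies at
  the 1e−3 level.
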