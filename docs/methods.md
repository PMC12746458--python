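# Methods

## Model

The optimizer treats SCF orbital optimization as minimization over the
nonredundant orbital-rotation parameters X (the occupied–virtual block of
an antisymmetric generator κ; for unrestricted determinants the α and β
blocks are concatenated, all transformations acting blockwise per spin).
At each outer iteration a gradient-enhanced Kriging (GEK) surrogate is
conditioned on the energies and gradients of the stored history (at most
20 points) and the next step is obtained on the surrogate, where exact
derivatives are cheap.

**Kernel.** Matérn 5/2 correlation over the anisotropic scaled distance.
The covariance matrix M holds kernel values plus all first and second
cross-derivatives between data points; prediction uses the centered form
E\*(x) = μ + v(x)ᵀM⁻¹(y − **1**μ). The two typeset conventions in
circulation (raw y vs centered y − **1**μ) differ by a constant shift
unless the covariance rows sum appropriately; the centered form is adopted
because it reproduces the data exactly *and* relaxes to the prior mean μ
far from all data. μ is set to the maximum data energy plus an offset of
10 hartree: large enough that the surrogate is bounded below by a bowl
around the data, small enough that the predicted variance stays a usable
step control. The predictor Hessian needs third kernel derivatives; they
are implemented in closed form through three radial factors that remain
finite at coincident points (the kernel is C⁴ there), with the symmetric
limit used at d = 0.

**Length scales.** Set noniteratively, lₖ = √(5(μ−E_max)/(3εₖ)), from the
eigenvalues εₖ of the projected diagonal guess Hessian, so that a
single-point surrogate has predictor curvature exactly εₖ (verified to
machine precision). Eigenvalues are floored at 0.025 hartree (configurable
`hessian_floor`) before the formula — the inverse square root otherwise
blows up on near-zero or negative guess curvatures. The floor value is a
documented knob; nothing in the method fixes it beyond "positive and small
against typical orbital-energy gaps".

**Variance restriction.** The step search on the surrogate is truncated
where the predicted variance reaches c·‖gʳ‖ with c = 0.3 by default
(`variance_coefficient`). The proportionality to the reduced gradient norm
makes the budget self-scaling: aggressive far from convergence, tight near
it. The constant itself is a design choice exposed in configuration; the
property suite (not any external value) validates it.

## Subspace

Candidate spanning vectors, in fixed insertion order (this decides which
near-dependent vectors get dropped): the m history displacements
(oldest first), the m history gradients, the current gradient, and one
expansion direction — at most 2m+2. Orthonormalization is modified
Gram–Schmidt with one re-orthogonalization pass and a relative drop
tolerance of 1e−8. The diagonal guess Hessian (orbital-energy differences
scaled consistently with the gradient prefactor, 4(εa−εi) restricted /
2(εa−εi) per spin unrestricted) is projected and diagonalized; the
eigenvector basis P̂ performs all projections, so projected-Hessian
eigenvalues and kernel axes coincide.

The expansion direction comes from either a GDIIS extrapolation over the
stored (x, g) pairs with quasi-Newton preconditioning by the diagonal
guess (reset rule: coefficients above 15 in magnitude discard the oldest
records), or a BFGS direction built from consecutive history pairs
(updates violating sᵀy > 1e−12‖s‖‖y‖ are skipped). Only the direction
enters the subspace, which bounds the method's sensitivity to the
extrapolation internals. The GDIIS comparator is a *GDIIS-like* construct:
error vectors are preconditioned gradients and the reset threshold is a
package choice.

## Coordinate and gradient transport

The reference orbitals are always the current iterate (the exponential map
is best behaved around κ = 0), so every accepted step rebases the history:

- **Coordinates.** From K = exp(−Δκ)exp(κ), SVD of the occupied–occupied
  block K_oo = VΣWᵀ gives κ̃ with block X̃ = −V·scos(Σ)·Wᵀ·K_voᵀ, where
  scos(x) = arccos(x)/√(1−x²) is evaluated through its Taylor series in
  t = arccos(x) near the removable point x = 1. A vanishing singular value
  (a 90° occupied rotation) aborts the rebase and the driver restarts its
  history from the current point.
- **Redundant-rotation factors.** The orthogonal U°, Uᵛ satisfying
  C̃ exp(κ̃) = C exp(κ)·blockdiag(U°, Uᵛ) are produced by the same SVD.
  Two transpose conventions are possible in typeset form; the implemented one is
  fixed by verifying the defining relation numerically (the alternative
  fails it by O(‖X‖²)), and is further pinned by the finite-difference
  invariant below.
- **Gradients.** Each record stores the gradient at its *own* orbitals,
  re-aligned by U°ᵀ(·)Uᵛ at every rebase; the gradient in the current
  frame is the derivative-of-the-exponential-map transport of that payload
  evaluated at the record's *current* coordinate X̃. Restricted to the
  occupied–virtual block the transport series contains only even powers of
  its argument (so its overall sign is immaterial), and is available both
  as the nested recursion Tₖ = (2XTₖ₋₁ᵀ − Tₖ₋₁Xᵀ)X − XXᵀTₖ₋₁ summed with
  1/(2k+1)! weights, and as a closed form from the SVD of X using
  singularity-free sinc combinations. The two agree to 1e−12 and both
  match a brute-force nested-commutator oracle. Evaluating the series at
  the record's own coordinate — rather than at the step Δκ — is the
  choice that makes transported gradients of *all* history points match
  central differences of the backend energy in the new frame (the
  decisive frame-consistency invariant, satisfied to ~1e−9 on toy HF
  surfaces over successive rebases; the Δκ variant is exact only for the
  most recent point and errs at third order for older ones).

Analytic backends live in a flat space: rebasing is coordinate
translation, gradients are frame-independent.

## Driver

Per iteration: evaluate (one Fock build), append the point, test
convergence (strict, simultaneous: |ΔE| < 1e−9 hartree, max|F_ov| <
1.5e−4, ‖Δκ‖ < 1e−3; analytic backends substitute the max gradient entry
for the Fock criterion), propose the step, apply it, rebase the history,
update the loosening factor. The first iteration, with an empty history,
takes a preconditioned steepest-descent step capped at norm 0.3.
Nonconvergence at `max_iter` (default 400) is a reported status.

**Microiterations.** Standard augmented-Hessian rational-function steps on
the surrogate, with an adaptive inner trust radius (initialized at half
the smallest characteristic length, shrunk when the surrogate energy
fails to decrease) and at most 200 microiterations. When a proposed
micro-step crosses the variance wall, the crossing is located by bisection
on the step scale (≤ 30 bisections, tolerance 1e−6 on the variance) so
the returned point sits on the wall. A zero variance budget returns a zero
step. Degenerate augmented eigenproblems fall back to a level-shifted
Newton step.

**Undershoot mitigation.** The loosening factor starts at 1; consecutive
steps within 5° multiply it by the golden ratio, a change above 20° resets
it, the dead zone in between leaves it alone. It enters as the rank-one
curvature scaling H̃ = WᵀHW applied during projection (never materializing
an n×n matrix), which lengthens the characteristic length along the
repeated direction.

**Baseline.** The r-GDIIS comparator shares the outer loop, history and
rebase plumbing and replaces the surrogate machinery by the
quasi-Newton-preconditioned GDIIS extrapolated point, capped at norm 0.5,
with the same reset rule and convergence test.

**Conditioning.** Covariance factorization attempts plain Cholesky, then a
1e−10 diagonal nugget, then drops the oldest data point and reassembles
(age pruning; condition-number pruning was considered and rejected for
determinism and simplicity). Exactly duplicated, consistent data survive
via the nugget.

## Synthetic fixtures and what they do (not) show

The Hartree–Fock backend covers H/He systems with s-type contracted
Gaussians (closed-form integrals through the zeroth Boys function,
≤ 10 basis functions): H₂ and HeH⁺ (restricted), an H₄ chain (restricted
singlet and unrestricted triplet) and an H₃ chain (unrestricted doublet),
all in a split-valence two-function-per-atom basis from the core-orbital
guess. These produce genuine coupled SCF surfaces — including
spin-polarized ones — and exercise every code path: subspace compression,
rebasing, transport, variance walls, both expansion predictors. They do
*not* probe near-degenerate transition-metal-like electronic structure,
large basis sets, or the convergence pathologies of production systems;
passing here demonstrates correctness of the machinery and qualitative
behavior (fewer Fock builds than the GDIIS baseline on these fixtures,
robust cross-method agreement of minima), not production-scale
performance. Problem sizes (n ≤ 22 rotation parameters, histories ≤ 20)
were chosen so the whole suite and the acceptance script run in seconds
to a few minutes on one CPU.

## Numerical choices

- Flattening X ↔ vector is row-major over the occupied index, fixed
  project-wide; α precedes β.
- Block order in M and y: energies first, then gradients grouped by data
  point — any consistent order works; this one is frozen for
  reproducible tests.
- Gradient prefactors (−4 restricted, −2 per spin unrestricted, from the
  occupied–virtual Fock block) are pinned by central differences rather
  than trusted from any convention, since a single global factor error
  would silently corrupt everything downstream.
- Variance values in (−1e−10, 0) from round-off are clamped to zero;
  larger negativity raises.
- Convergence ties resolve conservatively (strict inequalities).
- All randomness is seed-controlled; the optimizers themselves are
  deterministic, so equal configurations give byte-identical traces.

## Known limitations

- The integral engine is s-functions-only and capped at 10 basis
  functions by design; no DFT, no relativistic or density-fitting
  features.
- The GDIIS baseline approximates the production variant (error-vector
  choice, reset details); conclusions about *relative* iteration counts
  on the toy fixtures are indicative only.
- The closed-form transport assumes n_vir ≥ n_occ (the usual SCF
  situation); the series route has no such restriction.
- Variance is assumed monotone along the final micro-step segment when
  bisecting for the wall; pathological non-monotone segments would end
  slightly inside the feasible region, never outside the budget by more
  than the stated tolerance.
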