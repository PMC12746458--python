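# gekscf

Self-consistent-field (SCF) orbital optimization driven by a
gradient-enhanced Kriging surrogate model with restricted-variance steps,
plus a quasi-Newton GDIIS baseline, exercised on toy Hartree–Fock systems
and analytic surfaces.

## The problem and the method

SCF convergence — the iterative minimization of the Hartree–Fock (or
Kohn–Sham) energy over molecular orbitals — is usually driven by DIIS-type
extrapolation. This package implements an alternative: energies **and**
gradients of up to 20 previous iterations are interpolated by a
gradient-enhanced Kriging (GEK) model,

E\*(x) = μ + v(x)ᵀ M⁻¹ (y − **1**μ),

built with a Matérn 5/2 covariance, f(d) = (1 + √5·d + 5d²/3)·e^(−√5·d),
over the anisotropic distance d = √Σₖ((xₖ−x′ₖ)/lₖ)². The model reproduces
its data exactly and predicts a variance

s²(x) = (y − **1**μ)ᵀM⁻¹(y − **1**μ)/m · [1 − v(x)ᵀM⁻¹v(x)],

so steps are limited by model *uncertainty* (restricted-variance
optimization, RVO) instead of a fixed trust radius: the next iterate is
found by restricted-step rational-function (RS-RFO) microiterations on the
surrogate, truncated where the variance hits c·‖gʳ‖.

Three ingredients make this practical:

- **Subspace compression.** The model lives in a K ≤ 2m+2 dimensional
  subspace spanned by the stored displacements and gradients, the current
  gradient, and one cheap expansion direction (a GDIIS or BFGS displacement
  prediction — only its direction matters). The characteristic lengths are
  set noniteratively from the projected guess-Hessian eigenvalues,
  lₖ = √(5(μ−E_max)/(3εₖ)), so a single-point model has predictor
  curvature εₖ.
- **Undershoot mitigation.** On flat sloped regions the bounded surrogate
  systematically undershoots. When consecutive steps are near-parallel
  (< 5°), a loosening factor f_L grows by the golden ratio and softens the
  guess curvature along that direction (H̃ = WᵀHW with
  W = I + (1/f_L − 1)qqᵀ), lengthening subsequent steps; a direction change
  > 20° resets f_L to 1.
- **Exact coordinate/gradient transport.** Orbitals are parametrized as
  C′ = C·exp(κ) with κ the antisymmetric occupied–virtual generator. Since
  the reference orbitals move every iteration, stored coordinates are
  rebased through an SVD retraction (κ̃ from the occupied–occupied block of
  exp(−Δκ)exp(κ)) and stored gradients are transported by the derivative of
  the exponential map — implemented both as an even nested-commutator
  series and as a noniterative closed form, which agree to machine
  precision.

Backends: a minimal s-type Gaussian Hartree–Fock engine (H/He systems,
restricted and unrestricted, ≤ 10 basis functions, Boys-function closed
forms) and analytic surfaces (quadratics, a tilted slope, Rosenbrock).

## Worked example

```bash
$ printf '2\nh2\nH 0 0 0\nH 0.74 0 0\n' > h2.xyz
$ gekscf compare --system h2.xyz --basis 6-31g --out out/
   method  converged  iterations  final_energy  same_minimum
   rgdiis       True           7 -1.1267553117          True
sgek-diis       True           5 -1.1267553146          True
sgek-bfgs       True           5 -1.1267553146          True
```

All three optimizers converge H₂/6-31G from the core guess to the
restricted Hartree–Fock minimum (−1.12675531 hartree); the surrogate
variants need 5 Fock builds against 7 for the GDIIS baseline, the energies
agree within 10⁻⁸ hartree and the occupied orbital spaces coincide
(`same_minimum` uses the product of singular values of C₁ᵀSC₂ ≥ 1−10⁻⁶).
Convergence means, simultaneously: energy change < 10⁻⁹ hartree, max
occupied–virtual Fock element < 1.5×10⁻⁴, and step norm < 10⁻³.

The undershoot mitigation can be watched in isolation:

```bash
$ gekscf demo-slope
with_mitigation        displacement after 10 iterations: 29.8525  (final f_L=76.013)
without_mitigation     displacement after 10 iterations: 5.7147  (final f_L=1.000)
mitigation lengthens the path by a factor 5.22
```

On a constant slope the variance-restricted steps stall without the
loosening heuristic; with it, f_L climbs by golden-ratio multiples and the
optimizer covers > 5× the distance in the same 10 iterations.

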