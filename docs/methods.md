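# Methods

## The model

`morphocontract` implements a one-dimensional morphoelastic model of
post-burn skin contraction.  Six fields live on a stretch of dermis: the
lumped growth-factor/cytokine density *c* (g/cm³), fibroblasts *N* and
myofibroblasts *M* (cells/cm³), collagen ρ (g/cm³), the displacement
velocity *v* (cm/day) and the effective strain ε.  Morphoelasticity
decomposes the total deformation into a permanent (growth/shrinkage) part
and an elastic part, so the tissue can acquire the plastic contraction that
clinically presents as a contracture; ε measures the elastic distance to a
hypothetical relaxed configuration and evolves by

∂ε/∂t + v ∂ε/∂x + (ε − 1) ∂v/∂x = −ζ [N + η<sup>II</sup>M] c ε / (1 + a_c<sup>II</sup> c).

The four constituents obey reaction–diffusion–advection balances: Fickian
diffusion of *c* with Hill-type secretion by (myo)fibroblasts and
MMP-mediated breakdown; density-dependent diffusion D_F(N+M) and chemotaxis
χ_F z ∂c/∂x of the cell species with logistic growth N^(1+q)[1 − κ_F(N+M)],
differentiation k_F c N and apoptosis; collagen secretion and quadratic
proteolysis.  The momentum balance keeps inertia,

ρ_t (∂v/∂t + 2v ∂v/∂x) = ∂/∂x ( μ ∂v/∂x + E√ρ ε ) + ∂/∂x ( ξMρ/(R²+ρ²) ),

with a viscoelastic stress whose stiffness E√ρ tracks collagen and a
traction body force generated by myofibroblasts.  All constituents are
passively convected with v.

Around the healthy equilibrium (0, N̄, 0, ρ̄, 0, ε̄) two algebraic relations
close the parameter set: δ_N = r_F(1 − κ_F N̄) N̄^q and ρ̄ = √(k_ρ/δ_ρ).
Because q is a *consequence* of the other constants, the packaged default
stores it at full precision (−0.41506929…, printing as −0.4151); with the
4-digit print the equilibrium would be violated at the 4×10⁻⁴ level and
drift visibly over hundreds of days.

## Linear stability

Perturbations are expanded in Fourier modes; each mode obeys y′ + A y = 0
with a 6×6 matrix whose leading 4×4 block is lower triangular in the order
(c, M, N, ρ), so the eigenvalues are the four diagonal entries plus the
roots of the mechanical 2×2 block, λ = A₅₅/2 ± √(A₅₅² + 4A₅₆A₆₅)/2.  The
equilibrium is stable iff

1. δ_c ρ̄ ≥ k_c / a_c¹ (signaling decay beats secretion),
2. q δ_N ≤ κ_F r_F N̄^(1+q) (crowding),
3. ε̄ ≤ 1 (small-strain requirement),

and decay is monotonic (eigenvalues real) iff
μ ≥ √(ρ_t E √ρ̄ (1 − ε̄))/π at the slowest wave k = 1.

The Von Neumann (semi-discrete) counterpart replaces (2πk)² by
4sin²(πβh)/h² and (2πk) by sin(2πβh)/h on a uniform grid with constant
coefficients.  Both substitutions are non-negative where it matters, so the
continuous criteria imply the semi-discrete ones for *every* spacing h, and
the discrete monotonicity threshold h/tan(πβh)·√(ρ_t E√ρ̄(1−ε̄)) never
exceeds the continuous one.  The mode matrices are assembled from
hard-coded entries and are cross-checked in the test suite against (a) a
dense eigensolver, (b) an independently written finite-difference stencil +
DFT oracle, and (c) a central-difference Jacobian of the nonlinear kinetics.
Two entries admit more than one plausible reading and are fixed here by
consistency: the body-force coupling of the semi-discrete matrix follows
the stencil substitution exactly (no extra factor ½ — required by the h→0
limit; the entry affects no eigenvalue), and the strain factor in the
discrete discriminant is (1 − ε̄).

Stability is reported as Re λ ≥ 0 with tolerance 1e-12; exact equality is
flagged `marginal` ("stable (marginal)").  Gershgorin bounds are exposed as
a clearly secondary diagnostic only.

## Moving-grid finite-element solver

Linear elements on a mesh whose nodes move with the material velocity
(mesh velocity = v, so basis functions satisfy Dφ/Dt = 0).  With the
Leibniz–Reynolds transport theorem every conservative convection term
∂(zv)/∂x is absorbed into the motion of the mass matrix,
d/dt[M(t)z] = F(z), and the strain equation reduces *exactly* to the
material form d/dt∫εφ = ∫φ(∂v/∂x − αε) — the identity
−(ε−1)v_x + εv_x = v_x removes the nonlinear coefficient, so the strain
update is linear in v with no frozen factor.  The momentum equation is the
same conservative form with density ρ_t (2v v_x = ∂(v²)/∂x).

One implicit step solves the monolithic system over all six fields with
backward Euler and inner Picard iterations:

* every nonlinear coefficient (Hill factors, logistic terms, MMP inhibition,
  √ρ in the stress, the body force, the mesh geometry itself) is frozen at
  the previous iterate, so unknowns enter linearly;
* each equation is kept implicit in its own unknown where the coefficient
  is regular; the myofibroblast growth M^(1+q) is applied as an explicit
  source because M̄ = 0 makes an implicit M^q coefficient singular;
* the Picard stopping rule is a per-field relative max-norm update below
  1e-8 (at most 25 iterations).  The update tolerance, the quadrature
  (element-midpoint coefficients, lumped masses) and the absence of
  convection stabilization are choices of this package; the moving mesh
  removes the convective terms, so no SUPG-type stabilization is needed.
* unknowns are interleaved per node, giving a banded matrix of half
  bandwidth 11 factorized with LAPACK's banded solver.

Mass lumping is on by default; on uniform meshes the lumped diffusion
blocks are M-matrices and satisfy a discrete maximum principle (tested),
which is the motivation for lumping in the first place.  With the exactly
consistent parameter set the equilibrium is a machine-precision fixed point
of the step map for any Δt — the practical face of the A-stability of
backward Euler.

Blow-up is *signalled*, not hidden: singular step matrices, non-finite
solutions, mesh tangling, or Picard updates that fail to fall below 1e-2
after 25 iterations raise (or, under `simulate`, terminate the trajectory
with) a diagnostic carrying the last finite state.  Negative densities are
logged as monotonicity-loss warnings and the run continues, matching the
1D behaviour of the scheme (flux correction is out of scope).

Boundary data: c = 0, N = N̄, M = 0, v = 0 (Dirichlet) on physical
boundaries; ρ and ε carry no boundary rows (their characteristics are
vertical).  Half-domain runs place the Dirichlet data on the left end only
and treat the right end as the symmetry plane of the wound centre: v = 0
plus natural zero-flux for c, N, M.  A mirrored full-domain run (densities
even, velocity odd) agrees with the half-domain run to discretization
tolerance (tested).

## Scenarios (the synthetic initial conditions)

*Wound scenario* (convergence study): 10 cm domain, 4 cm wound plateau
centred, 1 cm ramps.  Inside the wound c = 10⁻⁸ g/cm³, N = 2000 cells/cm³,
ρ = 0.01125 g/cm³ (one tenth of their far-field equilibria for N, ρ);
M = v = ε = 0 everywhere.  Ramps blend by a half-period cosine, so the ramp
midpoint is the arithmetic mean.  Wound-edge material nodes (x = 3, 7 cm)
track the relative surface area of the wound, RSAW(t) = current marker
distance / initial distance.

*Perturbation scenario* (stability validation, half-domain [0, 1] cm):
N, ρ, v, ε are perturbed by sine waves of amplitudes 10 cells/cm³,
10⁻² g/cm³, 0.05 cm/day, 0.5; the convention here is that the wave number
k counts half periods on [0, 1], so every perturbation vanishes at both
ends and the Dirichlet data holds exactly.  The zero-equilibrium densities
M and c use non-negative bumps through 2k+1 uniform knots, zero at the end
knots, interior values alternating low/high starting low (3 and
6 cells/cm³; 0.5×10⁻¹⁵ and 2×10⁻¹⁵ g/cm³).  The bumps are shape-preserving
cubics (PCHIP): a natural interpolating cubic through the same knots
undershoots below zero near the end knots for k ≥ 5, which would violate
the required positivity of the densities, while the monotone cubic stays
within the knot range by construction.  The ε amplitude 0.5 about ε̄ = 0
keeps ε ≤ 1 everywhere.  Profiles are continuous functions sampled at the
nodes: refining the mesh changes samples, never the profile.

What these synthetic states do *not* emulate: real burn geometry, spatial
heterogeneity of material constants, stochastic cell behaviour, or
re-epithelialization.  Passing tests therefore demonstrate fidelity to the
stated mechanochemical model, not predictive accuracy for clinical wounds.

## Numerical experiments

*Convergence ladder*: node counts n ∈ {41, 81, 161, 321, 641, 1281}
(n − 1 elements, h = 10/(n−1), Δt = h², one simulated day), finest run as
reference.  Because meshes move, solutions are compared at *material* nodes
matched by initial coordinate; the ladder is nested, so the 41 coarse
material points and the wound-edge node exist on every grid.  Four error
norms per variable: the 41-point absolute-difference sum; trapezoid
approximations of ∫|z−z_h| and (∫(z−z_h)²)^½ on the reference mesh after
linear interpolation of the coarse run; the wound-edge material-node
difference (the precise quadrature and interpolation for these three are
this package's definitions); slopes by ordinary least squares on all
(log h, log ε) pairs.  The
acceptance script runs the full ladder; the test suite runs 41…321 against
a 641-node reference with the slope tolerance widened to ±0.3, keeping the
default test run inside a desk-scale budget.

*Stability-validation matrix*: half-domain, n = 500 elements, Δt = 0.5 day
(for the low-viscosity runs Δt = 0.01 until day 2, then 1 until day 50,
then 2).  δ_c ∈ {2, 3, 5}×10⁻⁴ cm⁶/(cells g day) and μ ∈ {1, 100}
(N day)/cm².  Outcomes are classified as
converged-to-equilibrium (every field's scaled end-state distance < 1%,
scales = equilibrium magnitude for N, ρ and the initial perturbation
amplitude for c, M, v, ε), blow-up (signalled by the solver), or
converged-to-new-equilibrium.  Because the shifted state *oscillates*
around its attractor, settling is judged on trailing-window means (three
windows of 5% of the run): a field has settled when the window-mean drift
is below 1% or shrinking.  The report always carries both the analytic
criterion verdict and the empirical outcome — the δ_c = 3×10⁻⁴ cell
violates the criterion yet settles on a shifted equilibrium, which an
independent root-find on the uniform kinetics (scipy fsolve) confirms to
within a few percent.

*Reversion*: from the day-1000 shifted state, c is reset to 0 and the run
continues (Δt = 0.5, 1400 days).  Recovery time of each constituent is the
first time it closes 95% of its gap to the healthy equilibrium and stays;
the expected ordering is myofibroblasts, then collagen, then fibroblasts —
consistent with the linear rates δ_M = 0.06/day, 2δ_ρN̄ρ̄ ≈ 0.0135/day and
|qδ_N| + κ_F r_F N̄^(1+q) ≈ 0.0085/day.

## Known limitations

* One spatial dimension only; no flux correction for negative densities;
  no adaptive time stepping beyond the explicit schedule.
* The Picard matrix freezes the secretion, differentiation, chemotaxis,
  crowding and body-force cross-couplings (they converge through the
  iteration); the test suite documents exactly which Jacobian entries
  live in the matrix and which in the loop.
* Event times in the unstable regime (when the blow-up occurs, when the
  shifted state is reached) depend on the seed-level amplitudes of the
  initial perturbation and on output cadence; they are reported but should
  be read as qualitative.  The attractor values themselves are robust.
* The classifier cannot distinguish "shifted equilibrium" from "very slow
  approach to the healthy one" on short horizons; validation runs use the
  published horizons (400–1200 days).
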