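# Methods

## The physical problem

A convex body `A` (a model cell) sits in an infinite diffusive medium.
Nutrient molecules diffuse with constant `D` and are taken up at the cell
surface through a coarse-grained *reactivity* field `k(R)` — absorbed flux
per unit area per unit local concentration — giving the Robin boundary
condition

    D ∇n(R)·ω̂(R) = k(R) n(R),   R ∈ ∂A,

with either a fixed concentration `n∞` at infinity (bulk source) or a point
source of rate `Φ_S`.  The steady-state total uptake is
`Φ_A[k] = D ∫_∂A ∇n·ω̂ dσ`.  The question the package answers: for a fixed
mean reactivity `K = k_ave R0 / D`, which distribution `k(R)` maximizes
`Φ_A`, and by how much does it beat the homogeneous distribution?

Internal units: `D = 1`, reference-sphere radius `R0 = 1`, `n∞ = 1`,
`Φ_S = 1`.  All bodies are rescaled to surface area `4π` (that of the unit
sphere), so shapes compete at fixed area, and bulk fluxes are reported in
Smoluchowski units `Φ_U[∞] = 4π D R0 n∞`, the uptake of a perfectly
absorbing unit sphere.

## Fly now: the reflective walk-on-spheres simulation

Absorption is *not* simulated.  Instead one simulation per shape records
how purely reflected Brownian walkers visit the surface:

1. **Launch.** Walkers start uniformly on the enclosing sphere `|p| = R_B`
   (bulk) or at the point source placed on that sphere.  By potential
   theory, a bulk walker entering through `∂B` carries flux share
   `Φ_B = 4π D R_B n∞`, uniformly over the sphere.
2. **Far field.** While farther than `d*` from the body, walk-on-spheres
   jumps: a uniform point on the sphere of radius `dist − δ` around the
   current position.  This samples the continuous diffusion exactly; the
   safety margin `δ` keeps jumps from landing closer than half a boundary
   layer to the surface, avoiding contact undersampling.
3. **Outside `∂B`.** The walker escapes to infinity with probability
   `1 − R_B/r`; otherwise it re-enters through `∂B` at a point drawn from
   the exterior harmonic measure, whose angular density
   `f(µ) ∝ (r²−R_B²)/(r²+R_B²−2 r R_B µ)^{3/2}` is sampled by a closed-form
   inverse CDF.  Both steps are exact, so the condition at infinity costs
   nothing.
4. **Boundary layer** (`dist ≤ d* = 4λ`).  Finite-step Brownian motion
   with time step `Δt = λ²/(4D)`.  A proposal landing inside the body is a
   *reflection event*: it is tallied against the equal-area axial surface
   domain (out of `M`) containing its nearest surface point, and the walker
   is reflected specularly across the local tangent plane.

The tallies `N_ij` over states {start, domain 1..M, escape} estimate the
discretized Brownian surface self-transport operator: the transition matrix
`p_ij` of the reflective chain.  Runs are split into contiguous subsample
blocks (default 1e5 particles at full scale, seeded independently from the
master seed) whose separate tallies provide error bars.

### Brownian substep distribution

The per-event absorption probability used later,
`p* = k √(π Δt / D)`, is the classical matching of a discrete-time
simulation to the Robin condition at a flat wall, and its derivation
assumes Euler–Maruyama dynamics, i.e. Gaussian increments.  The collision
frequency per unit boundary local time depends on the step distribution,
so the dressing and the walk must use the same discretization.  We verified
this empirically: with fixed-length isotropic steps of length λ the
homogeneous-sphere flux overshoots the closed form by ≈29% at `K = 0.1`,
while Gaussian increments (per-coordinate std `√(2DΔt) = λ/√2`) agree to
the subsample error.  Gaussian increments are therefore the default
(`gaussian_steps=True`); fixed-length steps remain available for
experimentation.  Gaussian tails very rarely (≈1e−9/step) penetrate deeper
than `d*`; such events are still reflected and merely counted, and only a
macroscopic rate (>0.1% of particles) raises an error, since that signals a
step size genuinely too large for the local curvature.

### Geometry

Bodies are axisymmetric about `z` and mirror-symmetric about `z = 0`:
sphere (`R = 1`), prolate spheroid (aspect ratio `γ = c/a ≥ 1`, semi-axes
solved in closed form from `2πa²(1 + γ asin(e)/e) = 4π`,
`e = √(1−1/γ²)`), and spherocylinder (relative length `L/r_c`, cap radius
`r_c = √(2/(2+L/r_c))`).  Distances are exact for the sphere and
spherocylinder.  For the spheroid the hot loop uses the certified lower
bound `max(a(|Tp|−1), |p|−c)` with `T = diag(1/a,1/a,1/c)` — it never
overestimates and has the exact sign, so walk-on-spheres jumps can never
enter the body and the Brownian layer is only ever enlarged (unbiased,
slightly slower).  At reflection events the exact nearest surface point is
found by 60 bisection steps on the stationarity condition of the squared
distance along the meridian, whose root is bracketed analytically on
`[0, π/2]`.

The `M` surface domains are equal-area bands along `z`, found by inverting
the cumulative area function: linear in `z` for sphere and spherocylinder
(Archimedes — both caps and cylinder have constant `dA/dz`), numerically
integrated and root-found for the spheroid (band areas equal to <1e−8).
Profiles are reported against the scaled axial coordinate
`cos β = z / z_max` of the band centres.

## Pay later: the dressed absorbing Markov chain

For a reactivity profile `{k_i}` each reflection event in domain `i`
absorbs with `p*_i = k_i √(πΔt/D) = (√π/2) k_i λ / D` and survives with
`q*_i = 1 − p*_i`.  `p*_i > 1` is an error, not a clip: it means the Robin
discretization is invalid for that `(k, λ)`.  First-step analysis of the
dressed chain gives two independent routes to the start-to-absorption
probability `P_A`:

    f = p* + diag(q*) P f,          P_A = p0·f
    V = p0 + Pᵀ diag(q*) V,         P_A = Σ_j V_j p*_j

solved densely (M ≤ a few hundred; two `M×M` solves per profile, ~tens of
microseconds at `M = 32`).  The two routes must agree to 1e−10 — this is
asserted on every solve.  Fluxes follow as `Φ_A = P_A Φ_B` (bulk; equal to
`P_A R_B` in Smoluchowski units) or `Φ_A = P_A Φ_S` (point source); local
flux densities divide each domain's absorbed share by its band area.
Never-visited domains get the fallback `p_esc = 1` with a warning and zero
local flux.

The "pay-now" oracle validates the whole construction: the same kernel can
flip an absorption coin with probability `p*_i` at every reflection, for
several profiles at once, *during* the reflective run.  The online
absorbed fraction and the a-posteriori Markov solve then derive from the
same trajectories and must agree at binomial resolution; this equivalence
is asserted in the test suite for both a homogeneous and a strongly
inhomogeneous profile.  (Oracle coin flips consume random draws, so tallies
with and without oracle profiles are different — determinism is
per-configuration.)

## Optimization

`Φ_A[k]` is maximized under `mean(k) = K`, `k_i ≥ 0`, with all evaluations
going through the one stored transition model.  Candidates come from
symmetric Dirichlet draws on the constraint simplex (`k = M K w`,
`w ~ Dir(1,…,1)`) and from a smooth two-parameter axial family
`k ∝ K (1 + a P₁(cos β) + b P₂(cos β))` (Legendre polynomials, clipped at
zero and iteratively rescaled to mean `K`).  The best candidates seed an
SLSQP polish with the equality constraint and box bounds; the upper bound
`min(M K, 0.999·2D/(√π λ))` keeps `p* ≤ 1` over the feasible set.  For
bulk sources on mirror-symmetric bodies an optional symmetric mode
optimizes only half the profile, halving the dimension and suppressing
noise-driven asymmetry.  `optimize_polynomial` restricts the search to the
two-parameter family outright; because it fits two numbers instead of `M`,
it is far more robust to sampling noise and is the preferred way to read
off the *shape* of the optimum at moderate particle numbers.

Because the model entries are noisy, the full `M`-dimensional optimizer
inevitably overfits a little: on the sphere — where symmetry makes every
profile of fixed mean equivalent — it reports a spurious in-sample gain of
~0.02% at `N = 1e5`, and the same profile shows a slightly *negative* gain
on held-out subsample blocks (the concavity penalty of betting on noise).
The test suite checks exactly this signature: no significant positive
held-out gain, in-sample overfit well below the genuine effects.

## Analytic references

* Homogeneous sphere: `Φ_A/Φ_U[∞] = K/(1+K)`; exterior hitting
  probability `R/r`.  These validate the pipeline end to end: the
  simulated pooled flux must match `K/(1+K)` within the subsample error
  (measured ≈ +0.16% relative at `λ = 0.004`, scaling roughly linearly in
  λ: ≈ +0.43% at `λ = 0.008`).
* Two-sphere toy: two homogeneous spheres far apart, combined area `4π`
  (`R1²+R2²=1`), additive fluxes `Φ(R,k) = R·kR/(1+kR)`.  With the
  area-weighted mean reactivity fixed (the analogue of the single-body
  budget; an unweighted-mean variant sits behind a flag), the gain of the
  best split over the uniform split, maximized jointly over split, budget
  and radius ratio on a dense grid with Nelder–Mead refinement, is
  **5.157%** at radius ratio ≈ 0.19 — the quantitative ceiling for how
  much redistribution toward curvature can ever pay for weakly coupled
  geometries.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `lam` (λ) | 0.001 | Brownian step length, `√(4DΔt)`; controls the discretization error of the dressing (≈0.04%/0.001 of λ on the sphere flux) |
| `d_star` | 4λ | boundary-layer half-width where the walk is Brownian |
| `delta` | 2λ | walk-on-spheres shrink margin |
| `r_b_factor` | 1.1 | `R_B` as a multiple of the body's half maximal dimension |
| `n_try` | 1e6 | particles per run (full scale) |
| `M` | 32 | equal-area surface domains |
| `subsample_size` | 1e5 | particles per error-bar block |
| `max_steps` / `max_events` | 1e7 / 65536 | per-particle caps; capped walkers are excluded and counted |

The validation and acceptance tests run a desk-scale version of these
conditions — `N = 1e5`, `λ = 0.004`, `M = 32` — with tolerances set by the
subsample spread and binomial counting statistics rather than by the
full-scale error bars.

## What the tests do and do not show

The stochastic checks exercise the sphere and the `γ = 3` spheroid with
bulk sources and the sphere with a point source.  They demonstrate:
correct exterior statistics (hitting probability, harmonic-measure
re-entry), correct Robin dressing (closed-form sphere flux across
`0.1 ≤ K ≤ 10`), the pay-now/pay-later equivalence, the pole-maximal
optimal profile on the spheroid, and the strong source-facing polarization
for point sources.  They do not reproduce the full-scale
(`N = 1e6, λ = 0.001`) error curves, the semi-analytic inhomogeneous
spheroid references, or time-resolved quantities; the gain *magnitude* for
the spheroid (~1% at full scale) is only bracketed (non-negative,
pole-maximal) at desk scale, where its size is comparable to the sampling
noise of a 32-parameter search.

## Known limitations

* Convex bodies of revolution only; general meshes and multi-body scenes
  are out of scope.
* The spheroid hot-loop distance is a lower bound; near the poles of very
  elongated bodies the Brownian layer is up to `γ`-fold thicker than
  requested, costing time but not accuracy.
* A saved configuration re-runs bitwise-identically only on the same
  numba/numpy versions (the kernel RNG is numpy's MT19937).
* Fluxes for reactivities near the regime bound `p* → 1` inherit O(λ)
  discretization error from the flat-wall matching formula.
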