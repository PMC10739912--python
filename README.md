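# robinflux

**Steady-state diffusional uptake through partially absorbing surfaces —
evaluate once, optimize for free.**

Cells and simple aquatic organisms absorb dissolved nutrients through
membrane transporters.  Coarse-grained, this is a diffusion problem with a
Robin boundary condition on the cell surface `∂A`:

    Δn = 0,   n(∞) = n∞,   D ∇n·ω̂ = k(R) n   on ∂A,

where the local reactivity `k(R)` is proportional to the transporter
density.  Given a fixed budget — the dimensionless mean reactivity
`K = k_ave R0/D` — *where on the surface should the transporters go to
maximize the total uptake `Φ_A[k]`?*

`robinflux` answers this with a two-stage ("fly now, pay later") Monte
Carlo method for convex bodies of revolution (sphere, prolate spheroid,
spherocylinder, all normalized to surface area 4π):

1. **Fly now** — a single walk-on-spheres simulation with *reflective*
   boundaries tallies how diffusing particles move between `M` equal-area
   surface domains, the start, and escape to infinity.  Exact
   potential-theory sampling (escape probability `R_B/r`, harmonic-measure
   re-entry) handles the condition at infinity; a thin Brownian layer
   (step λ) resolves surface contacts.
2. **Pay later** — for *any* reactivity profile `{k_i}`, each reflection
   in domain `i` absorbs with probability `p*_i = k_i √(πΔt/D)`; dressing
   the stored transition matrix with the survival factors `1 − p*_i` and
   solving a dense `M×M` linear system yields absorption probabilities and
   fluxes in microseconds — no re-simulation.  Optimization over profiles
   at fixed `K` (Dirichlet candidates + SLSQP) reuses the same statistics.

Fluxes are reported in Smoluchowski units `Φ_U[∞] = 4π D R0 n∞` (the
perfectly absorbing unit sphere); a homogeneous sphere obeys the closed
form `Φ_A/Φ_U[∞] = K/(1+K)`, which anchors the validation suite.

## Worked example

Simulate a γ = 3 prolate spheroid once, then evaluate and optimize on the
stored statistics:

```python
import numpy as np
from robinflux import (SimulationConfig, SourceSpec, ReactivityProfile,
                       OptimizationProblem, domain_partition, estimate_model,
                       evaluate_flux, make_body, optimize_polynomial, simulate)

body = make_body("prolate_spheroid", 3.0)     # semi-axes a=0.6378, c=1.9134
part = domain_partition(body, 32)             # 32 equal-area bands along z
cfg = SimulationConfig(lam=0.004, n_try=100_000, M=32, seed=202,
                       subsample_size=10_000)
counts = simulate(body, part, cfg, SourceSpec())   # the "fly now" stage

for K in (0.1, 1.0, 10.0):                    # the "pay later" stage
    res = evaluate_flux(counts, ReactivityProfile.homogeneous(K, 32), part)
    print(f"K={K:<4}  flux/Phi_U = {res.phi_smoluchowski:.4f}")

problem = OptimizationProblem(model=estimate_model(counts), K=1.0,
                              lam=0.004, source=SourceSpec(),
                              r_b=counts.config["r_b"], partition=part)
best = optimize_polynomial(problem)
print(f"gain {best.gain_percent:+.3f}%  "
      f"poles {best.profile[0]:.2f}/{best.profile[-1]:.2f}  "
      f"waist {best.profile[16]:.2f}")
```

Output (seed 202):

```
K=0.1   flux/Phi_U = 0.0911
K=1.0   flux/Phi_U = 0.5033
K=10.0  flux/Phi_U = 0.9263
gain +0.621%  poles 1.52/1.54  waist 0.77
```

The homogeneous fluxes sit close to the sphere's `K/(1+K)` (0.0909, 0.5,
0.9091) — shape barely matters for uptake at fixed area — and the optimal
profile roughly doubles the reactivity at the highly curved poles relative
to the waist, for a gain under a percent: redistributing a fixed uptake
budget over a convex body buys surprisingly little.

The same machinery from the shell:

```bash
robinflux simulate --shape prolate_spheroid --gamma 3 --n-try 100000 \
    --lam 0.004 --seed 202 --out runs/spheroid
robinflux evaluate runs/spheroid --k-mean 1.0
robinflux optimize runs/spheroid --k-mean 1.0 --symmetric
robinflux validate          # sphere vs closed form + two-sphere toy
```

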