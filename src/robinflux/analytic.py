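"""Closed-form references: the homogeneous sphere and the two-sphere toy.

Units throughout: D = 1, n_inf = 1, reference radius R0 = 1; fluxes are in
Smoluchowski units Phi_U[inf] = 4 pi D R0 n_inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize


def sphere_flux_homogeneous(K):
    """Steady-state flux into a homogeneous partially absorbing unit sphere,
    in units Phi_U[inf]: K/(1+K) with K = k R / D the dimensionless
    reactivity.  Tends to the Smoluchowski limit 1 as K -> infinity."""
    K = np.asarray(K, dtype=float)
    if (K < 0).any():
        raise ValueError("reactivity must be non-negative")
    out = K / (1.0 + K)
    return float(out) if out.ndim == 0 else out


def exterior_hit_probability(r, R: float) -> float:
    """Probability that a Brownian particle at radius r >= R ever hits the
    sphere of radius R (it escapes to infinity otherwise): R / r."""
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    if np.any(np.asarray(r) < R):
        raise ValueError("starting radius must satisfy r >= R")
    return R / r


def sphere_flux(R: float, k: float) -> float:
    """Flux into an isolated homogeneous sphere of radius R and reactivity
    k, in units Phi_U[inf]: R * (kR)/(1 + kR)."""
    return R * (k * R) / (1.0 + k * R)


@dataclass(frozen=True)
class TwoSphereToy:
    """Two far-apart homogeneous spheres with combined surface area 4 pi.

    R1^2 + R2^2 = 1 and the reactivity budget is fixed through the mean
    reactivity K: area-weighted (default), K = R1^2 k1 + R2^2 k2, or plain,
    K = (k1 + k2)/2.
    """

    R1: float
    R2: float
    k1: float
    k2: float
    weighting: str = "area"

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("radii must be positive")
        if abs(self.R1 ** 2 + self.R2 ** 2 - 1.0) > 1e-9:
            raise ValueError("combined surface area must equal 4 pi "
                             "(R1^2 + R2^2 = 1)")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("reactivities must be non-negative")
        if self.weighting not in ("area", "plain"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def K(self) -> float:
        """Mean reactivity under the chosen weighting."""
        if self.weighting == "area":
            return self.R1 ** 2 * self.k1 + self.R2 ** 2 * self.k2
        return 0.5 * (self.k1 + self.k2)

    def flux(self) -> float:
        """Total flux of the pair (far apart, so simply additive)."""
        return sphere_flux(self.R1, self.k1) + sphere_flux(self.R2, self.k2)


def two_sphere_gain(toy: TwoSphereToy) -> float:
    """Percent flux gain of the profile (k1, k2) over the homogeneous
    profile with the same mean reactivity on the same pair of spheres."""
    uniform = TwoSphereToy(toy.R1, toy.R2, toy.K, toy.K, toy.weighting)
    base = uniform.flux()
    if base <= 0:
        return 0.0
    return 100.0 * (toy.flux() / base - 1.0)


def _pair_from(q: float, K: float, s: float, weighting: str) -> TwoSphereToy:
    """Toy model from reduced coordinates: q = R2^2 in (0,1), s in [0,1]
    the share of the budget on sphere 1."""
    r1 = math.sqrt(1.0 - q)
    r2 = math.sqrt(q)
    if weighting == "area":
        k1 = K * s / (1.0 - q)
        k2 = K * (1.0 - s) / q
    else:
        k1 = 2.0 * K * s
        k2 = 2.0 * K * (1.0 - s)
    return TwoSphereToy(r1, r2, k1, k2, weighting)


def two_sphere_max_gain(weighting: str = "area", n_grid: int = 80,
                        refine: bool = True):
    """Global maximum percent gain of the two-sphere toy, optimized jointly
    over the radius ratio, the mean reactivity and the reactivity split.

    A dense grid over (q = R2^2, log10 K, split) locates the basin; a
    Nelder-Mead polish refines it.  Returns (gain_percent, argmax_dict).
    """
    q = np.linspace(0.02, 0.98, n_grid)
    K = np.logspace(-2.5, 2.5, n_grid)
    s = np.linspace(0.0, 1.0, n_grid)
    qg, kg, sg = np.meshgrid(q, K, s, indexing="ij")
    r1 = np.sqrt(1.0 - qg)
    r2 = np.sqrt(qg)
    if weighting == "area":
        k1 = kg * sg / (1.0 - qg)
        k2 = kg * (1.0 - sg) / qg
    else:
        k1 = 2.0 * kg * sg
        k2 = 2.0 * kg * (1.0 - sg)

    def vec_flux(r, k):
        return r * (k * r) / (1.0 + k * r)

    flux = vec_flux(r1, k1) + vec_flux(r2, k2)
    base = vec_flux(r1, kg) + vec_flux(r2, kg)
    gain = 100.0 * (flux / base - 1.0)
    idx = np.unravel_index(np.argmax(gain), gain.shape)
    best = (float(qg[idx]), float(kg[idx]), float(sg[idx]))
    best_gain = float(gain[idx])

    if refine:
        def neg(x):
            qq = 1.0 / (1.0 + math.exp(-x[0]))    # logit-transformed q
            kk = 10.0 ** x[1]
            ss = 1.0 / (1.0 + math.exp(-x[2]))
            return -two_sphere_gain(_pair_from(qq, kk, ss, weighting))

        x0 = [math.log(best[0] / (1.0 - best[0])), math.log10(best[1]),
              math.log(max(best[2], 1e-9) / max(1.0 - best[2], 1e-9))]
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        if not res.success and -res.fun < best_gain:
            raise RuntimeError(f"two-sphere refinement failed: {res.message}")
        if -res.fun >= best_gain:
            best_gain = float(-res.fun)
            qq = 1.0 / (1.0 + math.exp(-res.x[0]))
            best = (qq, 10.0 ** res.x[1], 1.0 / (1.0 + math.exp(-res.x[2])))
    toy = _pair_from(*best, weighting)
    return best_gain, {"R1": toy.R1, "R2": toy.R2, "k1": toy.k1, "k2": toy.k2,
                       "K": toy.K, "radius_ratio": toy.R2 / toy.R1,
                       "weighting": weighting}
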