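"""Absorbing-Markov-chain flux evaluation — the "pay later" half.

The reflective simulation gives bare transition probabilities p_ij between
the start state, the M surface domains and escape.  For a reactivity
profile {k_i} each reflection event in domain i absorbs the particle with
probability p*_i = k_i sqrt(pi dt / D) (the Robin discretization of Singer
et al., with dt = lambda^2 / 4D), so the bare chain is "dressed" by the
survival factors q*_i = 1 - p*_i.  First-step analysis of the dressed
chain then yields, for *any* profile and at the cost of two dense M x M
solves:

    f_i  = p*_i + q*_i sum_j P_ij f_j      (absorption prob. after a
                                            reflection in domain i)
    V_j  = p0_j + sum_i V_i q*_i P_ij      (expected dressed visits)

with P_A = sum_m p0_m f_m = sum_j V_j p*_j the start-to-absorption
probability, and the steady-state fluxes following from
Phi_A = P_A * Phi_B (bulk) or P_A * Phi_S (point source).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .geometry import DomainPartition
from .wos import SourceSpec, TransitionCounts

FOUR_PI = 4.0 * math.pi


class RegimeError(ValueError):
    """The Robin discretization is invalid (some p* > 1)."""


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic normalization of a TransitionCounts tally."""

    p0: np.ndarray        # (M,) start -> domain
    p0_esc: float         # start -> escape
    P: np.ndarray         # (M, M) domain -> domain
    p_esc: np.ndarray     # (M,) domain -> escape
    n_particles: int      # completed particles behind the start row
    visits: np.ndarray = field(default=None, repr=False)  # (M,) raw visit counts

    @property
    def M(self) -> int:
        return self.p0.shape[0]

    def validate(self, tol: float = 1e-12) -> None:
        if abs(self.p0_esc + self.p0.sum() - 1.0) > tol:
            raise ValueError("start row does not sum to 1")
        resid = np.abs(self.P.sum(axis=1) + self.p_esc - 1.0)
        if np.any(resid > tol):
            raise ValueError("a surface row does not sum to 1")
        if (self.p0 < 0).any() or (self.P < 0).any() or (self.p_esc < 0).any():
            raise ValueError("negative transition probability")


@dataclass(frozen=True)
class ReactivityProfile:
    """M non-negative domain reactivities in units D/R0."""

    k: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        if (k < 0).any():
            raise ValueError("reactivities must be non-negative")
        object.__setattr__(self, "k", k)

    @property
    def M(self) -> int:
        return self.k.shape[0]

    @property
    def mean(self) -> float:
        """Dimensionless mean reactivity K = k_ave R0 / D (R0 = D = 1)."""
        return float(self.k.mean())

    @classmethod
    def homogeneous(cls, K: float, M: int) -> "ReactivityProfile":
        return cls(np.full(M, float(K)))

    @classmethod
    def with_mean(cls, values, K: float) -> "ReactivityProfile":
        """Rescale non-negative weights to mean K."""
        v = np.asarray(values, dtype=float)
        if (v < 0).any():
            raise ValueError("weights must be non-negative")
        m = v.mean()
        if m <= 0:
            raise ValueError("weights must have positive mean")
        return cls(v * (K / m))


@dataclass
class AbsorptionResult:
    """Dressed-chain solution for one reactivity profile."""

    f: np.ndarray                   # (M,) absorption prob. from a reflection
    P_A: float                      # start-to-absorption probability
    absorbed_by_domain: np.ndarray  # (M,) absorbed fraction of particles
    visits: np.ndarray              # (M,) expected dressed visits per particle
    p_star: np.ndarray              # (M,) per-event absorption probabilities
    phi_total: float | None = None        # flux in source units (see units_note)
    phi_smoluchowski: float | None = None  # flux / Phi_U[inf] (bulk only)
    local_flux: np.ndarray | None = None   # per-domain flux density
    zero_visit_domains: np.ndarray | None = None
    units_note: str = ""


def estimate_model(counts: TransitionCounts) -> TransitionModel:
    """Normalize transition tallies row-by-row into probabilities.

    Rows with no outgoing transitions (never-visited domains) fall back to
    p_esc = 1 with a warning; they carry zero weight in any flux.
    """
    c = np.asarray(counts.counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative transition counts")
    M = counts.M
    esc = M + 1
    row0 = c[0]
    tot0 = row0.sum()
    if tot0 <= 0:
        raise ValueError("no launched particles in the start row")
    p0 = row0[1:esc] / tot0
    p0_esc = row0[esc] / tot0
    P = np.zeros((M, M))
    p_esc = np.zeros(M)
    visits = c[1:esc].sum(axis=1)
    empty = visits <= 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} surface domain(s) were never "
                      "visited; treating them as absorbing-to-escape",
                      RuntimeWarning)
    for i in range(M):
        row = c[1 + i]
        tot = row.sum()
        if tot <= 0:
            p_esc[i] = 1.0
            continue
        P[i] = row[1:esc] / tot
        p_esc[i] = row[esc] / tot
    model = TransitionModel(p0=p0, p0_esc=float(p0_esc), P=P, p_esc=p_esc,
                            n_particles=int(tot0), visits=visits)
    model.validate(1e-10)
    return model


def block_models(counts: TransitionCounts) -> list[TransitionModel]:
    """Per-subsample-block models (for error estimation)."""
    out = []
    for b in range(counts.n_blocks):
        sub = TransitionCounts(
            counts=counts.block_counts[b], block_counts=counts.block_counts[b:b + 1],
            M=counts.M, n_try=int(counts.block_counts[b][0].sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(estimate_model(sub))
    return out


def absorption_prob_per_event(k, lam: float, D: float = 1.0):
    """Per-reflection-event absorption probability of the Robin condition:
    p* = k sqrt(pi dt / D) with dt = lambda^2/(4 D), i.e. p* =
    (sqrt(pi)/2) k lambda / D.  Raises RegimeError if any p* exceeds 1."""
    k = np.asarray(k, dtype=float)
    p = k * (math.sqrt(math.pi) * lam) / (2.0 * D)
    bad = np.nonzero(np.atleast_1d(p) > 1.0)[0]
    if bad.size:
        raise RegimeError(
            f"p* > 1 in domain(s) {bad.tolist()}: reactivity {np.max(k):g} is "
            f"too large for Brownian step {lam:g}; the Robin discretization "
            "breaks down")
    return float(p) if p.ndim == 0 else p


def solve_absorption(model: TransitionModel, profile: ReactivityProfile,
                     lam: float, D: float = 1.0,
                     check_tol: float = 1e-10) -> AbsorptionResult:
    """Solve the dressed absorbing chain for one reactivity profile."""
    if profile.M != model.M:
        raise ValueError(f"profile has M={profile.M}, model has M={model.M}")
    p_star = absorption_prob_per_event(profile.k, lam, D)
    q = 1.0 - p_star
    M = model.M
    A = np.eye(M) - q[:, None] * model.P
    try:
        f = linalg.solve(A, p_star)
    except linalg.LinAlgError as err:  # pragma: no cover - degenerate input
        raise ValueError(f"singular dressed chain: {err}") from err
    f = np.clip(f, 0.0, 1.0)
    P_A = float(model.p0 @ f)
    # expected dressed visits: V = p0 + P^T diag(q) V
    B = np.eye(M) - model.P.T * q[None, :]
    V = linalg.solve(B, model.p0)
    absorbed = V * p_star
    alt = float(absorbed.sum())
    if abs(alt - P_A) > check_tol * max(1.0, abs(P_A)):
        raise ValueError(
            f"first-passage and visit-count routes disagree: {P_A} vs {alt}")
    zero = model.visits <= 0 if model.visits is not None else np.zeros(M, bool)
    return AbsorptionResult(f=f, P_A=P_A, absorbed_by_domain=absorbed,
                            visits=V, p_star=p_star,
                            zero_visit_domains=zero)


def total_flux(result: AbsorptionResult, source: SourceSpec, r_b: float,
               partition: DomainPartition | None = None,
               D: float = 1.0) -> AbsorptionResult:
    """Attach steady-state fluxes to an absorption solution.

    Bulk source: every particle entering the enclosing sphere carries a
    share of the perfectly-absorbing flux Phi_B = 4 pi D R_B n_inf, so
    Phi_A = P_A Phi_B; in Smoluchowski units Phi_U[inf] = 4 pi D R0 n_inf
    (R0 = 1) this is P_A * R_B.  Point source: Phi_A = P_A * Phi_S.
    """
    if source.kind == "bulk":
        phi_b = FOUR_PI * D * r_b * source.n_inf
        result.phi_total = result.P_A * phi_b
        result.phi_smoluchowski = result.phi_total / (FOUR_PI * D * source.n_inf)
        result.units_note = ("phi_total in absolute units (D=1, n_inf given); "
                             "phi_smoluchowski in units Phi_U[inf] = 4 pi D R0 n_inf")
        carried = phi_b
    else:
        result.phi_total = result.P_A * source.phi_s
        result.phi_smoluchowski = None
        result.units_note = "phi_total in units of the source rate Phi_S"
        carried = source.phi_s
    if partition is not None:
        with np.errstate(invalid="ignore"):
            lf = result.absorbed_by_domain * carried / partition.domain_areas
        lf[~np.isfinite(lf)] = 0.0
        result.local_flux = lf
    return result


def evaluate_flux(counts: TransitionCounts, profile: ReactivityProfile,
                  partition: DomainPartition | None = None,
                  model: TransitionModel | None = None) -> AbsorptionResult:
    """One-call pay-later evaluation: counts + profile -> fluxes."""
    if model is None:
        model = estimate_model(counts)
    lam = counts.config.get("lam", 0.001)
    D = counts.config.get("D", 1.0)
    src = SourceSpec.from_dict(counts.source) if counts.source else SourceSpec()
    r_b = counts.config.get("r_b", 1.1)
    res = solve_absorption(model, profile, lam, D)
    return total_flux(res, src, r_b, partition, D)


@dataclass
class SubsampleErrors:
    """Per-block flux estimates and the pooled estimate."""

    block_flux: np.ndarray    # per-block Phi (source units)
    pooled_flux: float        # flux from the summed counts
    spread: float             # std of the block estimates (ddof=1)
    sem: float                # spread / sqrt(n_blocks)

    @property
    def relative_sem(self) -> float:
        return self.sem / abs(self.pooled_flux) if self.pooled_flux else np.inf


def subsample_errors(counts: TransitionCounts, profile: ReactivityProfile,
                     partition: DomainPartition | None = None) -> SubsampleErrors:
    """Flux per contiguous subsample block, plus the pooled estimate.

    The pooled estimate is computed from the summed counts and, by count
    additivity, equals the particle-weighted mean of the block estimates.
    """
    lam = counts.config.get("lam", 0.001)
    D = counts.config.get("D", 1.0)
    src = SourceSpec.from_dict(counts.source) if counts.source else SourceSpec()
    r_b = counts.config.get("r_b", 1.1)
    flux = []
    for m in block_models(counts):
        res = total_flux(solve_absorption(m, profile, lam, D), src, r_b, None, D)
        flux.append(res.phi_total)
    flux = np.asarray(flux)
    pooled = evaluate_flux(counts, profile, partition).phi_total
    spread = float(flux.std(ddof=1)) if flux.size > 1 else np.inf
    return SubsampleErrors(block_flux=flux, pooled_flux=float(pooled),
                           spread=spread,
                           sem=spread / math.sqrt(max(flux.size, 1)))
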