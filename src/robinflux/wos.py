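"""Reflective walk-on-spheres engine — the "fly now" half of the method.

Particles are launched either uniformly from the enclosing sphere of radius
R_B (bulk source, concentration n_inf at infinity) or from a fixed point
source placed on that sphere.  Far from the body they move by exact
walk-on-spheres jumps; outside the enclosing sphere they either escape to
infinity (probability 1 - R_B/r) or re-enter through the sphere at a point
drawn from the exterior first-passage (harmonic) measure; within a thin
boundary layer of width d* they revert to finite-step Brownian motion with
step length lambda.  A Brownian proposal landing inside the body is a
*reflection event*: it is tallied against the equal-area surface domain of
its nearest surface point and the particle is specularly reflected back
out.  The tallies N_ij over states {start, domain 1..M, escape} are the raw
material for the "pay later" absorption solve in :mod:`robinflux.markov`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import Body, DomainPartition, GeometryError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the reflective simulation.

    Units: the diffusion constant D = 1 and the reference-sphere radius
    R0 = 1.  The Brownian step is lambda = sqrt(4 D dt); the boundary-layer
    width defaults to d* = 4 lambda and the walk-on-spheres safety margin to
    delta = 2 lambda.  R_B defaults to 1.1 x the body's half maximal
    dimension.
    """

    lam: float = 0.001
    d_star: float | None = None
    delta: float | None = None
    r_b: float | None = None
    r_b_factor: float = 1.1
    n_try: int = 1_000_000
    M: int = 32
    seed: int = 0
    subsample_size: int = 100_000
    max_steps: int = 10_000_000
    max_events: int = 1 << 16
    gaussian_steps: bool = True
    D: float = 1.0

    def resolved(self, body: Body) -> "SimulationConfig":
        """Fill the lambda-derived and body-derived defaults."""
        d_star = 4.0 * self.lam if self.d_star is None else self.d_star
        delta = 2.0 * self.lam if self.delta is None else self.delta
        r_b = self.r_b_factor * body.max_half_extent if self.r_b is None else self.r_b
        if r_b <= body.max_half_extent:
            raise ValueError("R_B must exceed the body's half maximal dimension")
        if not delta < d_star:
            raise ValueError("need delta < d_star so WoS jumps stop short of the surface")
        return replace(self, d_star=d_star, delta=delta, r_b=r_b)

    @property
    def dt(self) -> float:
        """Brownian time step, from lambda = sqrt(4 D dt)."""
        return self.lam ** 2 / (4.0 * self.D)

    def to_dict(self) -> dict:
        return {"lam": self.lam, "d_star": self.d_star, "delta": self.delta,
                "r_b": self.r_b, "r_b_factor": self.r_b_factor,
                "n_try": self.n_try, "M": self.M, "seed": self.seed,
                "subsample_size": self.subsample_size,
                "max_steps": self.max_steps, "max_events": self.max_events,
                "gaussian_steps": self.gaussian_steps, "D": self.D}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class SourceSpec:
    """Bulk source (fixed concentration n_inf at infinity) or point source
    of rate Phi_S at position s, with |s| = R_B by construction."""

    kind: str = "bulk"              # "bulk" | "point"
    n_inf: float = 1.0
    s: tuple[float, float, float] | None = None
    phi_s: float = 1.0

    def __post_init__(self):
        if self.kind not in ("bulk", "point"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "point" and self.s is None:
            raise ValueError("point source requires a position s")

    @property
    def s_radius(self) -> float:
        return float(np.linalg.norm(self.s)) if self.s is not None else 0.0

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_inf": self.n_inf,
                "s": list(self.s) if self.s is not None else None,
                "phi_s": self.phi_s}

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        s = tuple(d["s"]) if d.get("s") is not None else None
        return cls(d["kind"], d.get("n_inf", 1.0), s, d.get("phi_s", 1.0))


@dataclass
class TransitionCounts:
    """Integer transition tallies of the reflective simulation.

    ``counts[i, j]`` counts transitions from state i to state j, with
    states 0 = start, 1..M = reflection in domain m, M+1 = escape.
    ``block_counts`` keeps the per-subsample tallies used for error bars;
    they sum to ``counts``.
    """

    counts: np.ndarray                       # (M+2, M+2) int64, pooled
    block_counts: np.ndarray                 # (B, M+2, M+2) int64
    M: int
    n_try: int
    n_capped: int = 0
    n_bad_reflect: int = 0
    config: dict = field(default_factory=dict)
    body: dict = field(default_factory=dict)
    source: dict = field(default_factory=dict)
    block_seeds: list = field(default_factory=list)
    online: np.ndarray | None = None         # (n_profiles, M) oracle tallies
    online_blocks: np.ndarray | None = None  # (B, n_profiles, M)

    @property
    def n_completed(self) -> int:
        return self.n_try - self.n_capped

    @property
    def n_blocks(self) -> int:
        return self.block_counts.shape[0]

    @property
    def escape_state(self) -> int:
        return self.M + 1

    def fraction_reflected(self) -> float:
        """Fraction of completed particles with at least one reflection."""
        direct = self.counts[0, self.escape_state]
        return 1.0 - direct / self.n_completed

    def state_names(self) -> list[str]:
        width = max(3, len(str(self.M - 1)))
        return (["start"] + [f"d{m:0{width}d}" for m in range(self.M)]
                + ["escape"])

    def check_conservation(self) -> None:
        """Inflow equals outflow at every surface state; the start emits and
        the escape state absorbs exactly the completed particles."""
        c = self.counts
        out_flow = c.sum(axis=1)
        in_flow = c.sum(axis=0)
        if out_flow[0] != self.n_completed:
            raise ValueError("start-state outflow does not match particle count")
        if in_flow[self.escape_state] != self.n_completed:
            raise ValueError("escape-state inflow does not match particle count")
        surf = slice(1, self.M + 1)
        if not np.array_equal(out_flow[surf], in_flow[surf]):
            raise ValueError("flow not conserved at a surface state")


# -- elementary moves (reference implementations, also used in tests) ------

def sample_launch(source: SourceSpec, r_b: float, rng: np.random.Generator):
    """Initial position: uniform on the sphere |p| = R_B for a bulk source,
    the fixed point s for a point source."""
    if source.kind == "point":
        return np.asarray(source.s, dtype=float)
    z = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - z * z))
    return r_b * np.array([s * math.cos(phi), s * math.sin(phi), z])


def wos_move(body: Body, point, delta: float, rng: np.random.Generator):
    """One walk-on-spheres jump: uniform on the sphere of radius
    (distance to body) - delta around the current point."""
    d = body.distance_lower_bound(point)
    rad = d - delta
    if rad <= 0.0:
        raise ValueError("WoS jump radius <= 0: caller should be in Brownian mode")
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return np.asarray(point, dtype=float) + rad * u


def brownian_move(point, lam: float, rng: np.random.Generator,
                  gaussian: bool = False):
    """One Brownian substep proposal: a fixed-length isotropic step of
    length lambda (default) or a Gaussian increment with the same dt."""
    if gaussian:
        return np.asarray(point, dtype=float) + rng.normal(
            scale=lam / math.sqrt(2.0), size=3)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return np.asarray(point, dtype=float) + lam * u


def exterior_update(point, r_b: float, rng: np.random.Generator):
    """Handle a particle outside the enclosing sphere: return ``None`` if it
    escapes to infinity (probability 1 - R_B/r), otherwise its first-passage
    re-entry point on the sphere |p| = R_B."""
    p = np.asarray(point, dtype=float)
    r = float(np.linalg.norm(p))
    if r <= r_b:
        raise ValueError("exterior_update requires |point| > R_B")
    if rng.random() > r_b / r:
        return None
    mu = _kernels.sample_return_mu(r, r_b, rng.random())
    axis = p / r
    # orthonormal frame around the axis
    v = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = v - np.dot(v, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    psi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - mu * mu))
    return r_b * (mu * axis + s * (math.cos(psi) * e1 + math.sin(psi) * e2))


def return_mu_pdf(mu, r: float, r_b: float):
    """Density of mu = cos(landing angle) for first-passage re-entry,
    conditioned on return (normalized on [-1, 1])."""
    mu = np.asarray(mu, dtype=float)
    return (0.5 * r * (r * r - r_b * r_b)
            / (r * r + r_b * r_b - 2.0 * r * r_b * mu) ** 1.5)


def run_particle(body: Body, partition: DomainPartition,
                 config: SimulationConfig, source: SourceSpec,
                 rng: np.random.Generator) -> list[int]:
    """Pure-Python single-particle walk returning the visited state sequence
    ``[0, m1, m2, ..., M+1]``.  Reference implementation of the compiled
    kernel, for inspection and small-scale tests."""
    cfg = config.resolved(body)
    if source.kind == "point":
        cfg = replace(cfg, r_b=source.s_radius)
    p = sample_launch(source, cfg.r_b, rng)
    record = [0]
    steps = 0
    while True:
        steps += 1
        if steps > cfg.max_steps:
            raise RuntimeError("particle exceeded the step cap")
        r = float(np.linalg.norm(p))
        if r > cfg.r_b * (1.0 + 1e-12):
            nxt = exterior_update(p, cfg.r_b, rng)
            if nxt is None:
                record.append(partition.M + 1)
                return record
            p = nxt
            continue
        d = body.distance_lower_bound(p)
        if d > cfg.d_star:
            p = wos_move(body, p, cfg.delta, rng)
            continue
        q = brownian_move(p, cfg.lam, rng, cfg.gaussian_steps)
        if body.distance_lower_bound(q) < 0.0:
            s, _ = body.nearest_surface_point(q)
            m = partition.domain_of(s[2])
            record.append(m + 1)
            p = body.reflect_into_layer(q, max_depth=cfg.d_star)
        else:
            p = q


# -- main driver -----------------------------------------------------------

def simulate(body: Body, partition: DomainPartition, config: SimulationConfig,
             source: SourceSpec,
             oracle_profiles: np.ndarray | None = None) -> TransitionCounts:
    """Run the full reflective simulation and tally transitions.

    Parameters
    ----------
    oracle_profiles : array (n_profiles, M), optional
        Per-event absorption probabilities p* for the online ("pay now")
        absorption oracle.  For each profile, every launched particle flips
        an absorption coin at each reflection until first absorbed; the
        per-domain first-absorption tallies are stored in ``online`` /
        ``online_blocks``.

    The run is split into contiguous subsample blocks of
    ``config.subsample_size`` particles, each with a child seed spawned from
    ``config.seed``; identical configuration and seed give bitwise-identical
    counts.
    """
    cfg = config.resolved(body)
    if partition.M != cfg.M:
        raise ValueError(f"partition has M={partition.M} but config.M={cfg.M}")
    M = cfg.M
    if oracle_profiles is None:
        pstar = np.zeros((0, M))
    else:
        pstar = np.atleast_2d(np.asarray(oracle_profiles, dtype=float))
        if pstar.shape[1] != M:
            raise ValueError("oracle profile length does not match M")
        if np.any((pstar < 0) | (pstar > 1)):
            raise ValueError("oracle p* values must lie in [0, 1]")

    sizes = []
    remaining = int(cfg.n_try)
    while remaining > 0:
        take = min(cfg.subsample_size, remaining)
        sizes.append(take)
        remaining -= take
    n_blocks = max(len(sizes), 1)
    if not sizes:
        sizes = [0]
    seeds = [int(s) & 0x7FFFFFFF for s in
             np.random.SeedSequence(cfg.seed).generate_state(n_blocks, np.uint32)]

    if source.kind == "point":
        s_pos = np.asarray(source.s, dtype=float)
        r_s = float(np.linalg.norm(s_pos))
        # the source defines the enclosing sphere
        if abs(r_s - cfg.r_b) > 1e-9:
            if r_s <= body.max_half_extent:
                raise ValueError("point source must lie outside the body")
            cfg = replace(cfg, r_b=r_s)
        use_point = True
    else:
        s_pos = np.zeros(3)
        use_point = False

    block_counts = np.zeros((n_blocks, M + 2, M + 2), dtype=np.int64)
    online_blocks = np.zeros((n_blocks, pstar.shape[0], M), dtype=np.int64)
    n_capped = 0
    n_bad = 0
    for b, (size, seed) in enumerate(zip(sizes, seeds)):
        c, onl, capped, bad = _kernels.run_block(
            body.kind_code, body.param_a, body.param_c,
            partition.band_edges, cfg.r_b, cfg.lam, cfg.d_star, cfg.delta,
            size, seed, use_point, s_pos[0], s_pos[1], s_pos[2],
            pstar, cfg.gaussian_steps, cfg.max_events, cfg.max_steps)
        block_counts[b] = c
        online_blocks[b] = onl
        n_capped += capped
        n_bad += bad
    if n_capped:
        warnings.warn(f"{n_capped} particle(s) exceeded the step cap and were "
                      "excluded from the tallies", RuntimeWarning)
    if n_bad:
        # Gaussian increments have an unbounded tail, so isolated deep
        # penetrations are expected at rate ~1e-9/step; only a substantial
        # fraction signals a step size too large for the local curvature.
        if n_bad > max(10, 1e-3 * cfg.n_try):
            raise GeometryError(
                f"{n_bad} reflections penetrated deeper than the boundary "
                "layer; the Brownian step is too large for the local curvature")
        warnings.warn(f"{n_bad} reflection(s) penetrated deeper than the "
                      "boundary layer (Gaussian tail)", RuntimeWarning)
    tc = TransitionCounts(
        counts=block_counts.sum(axis=0),
        block_counts=block_counts,
        M=M, n_try=int(cfg.n_try), n_capped=n_capped, n_bad_reflect=n_bad,
        config=cfg.to_dict(), body=body.to_dict(), source=source.to_dict(),
        block_seeds=seeds,
        online=online_blocks.sum(axis=0) if pstar.shape[0] else None,
        online_blocks=online_blocks if pstar.shape[0] else None)
    return tc
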