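"""Convex axisymmetric bodies normalized to the reference-sphere surface area.

All bodies are symmetric about the z axis and about z = 0, centred at the
origin, and scaled so that their surface area equals that of the unit
sphere, 4*pi.  The unit of length is the reference-sphere radius R0 = 1.

Supported shapes:

* ``sphere`` — the reference sphere, radius 1;
* ``prolate_spheroid`` — semi-axes (a, a, c), aspect ratio gamma = c/a >= 1;
* ``spherocylinder`` — a right circular cylinder of length L capped by two
  hemispheres of radius r_c, parametrized by the relative length
  L_rel = L / r_c >= 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from . import _kernels
from ._kernels import KIND_SPHERE, KIND_SPHEROCYLINDER, KIND_SPHEROID

_KIND_CODES = {
    "sphere": KIND_SPHERE,
    "prolate_spheroid": KIND_SPHEROID,
    "spherocylinder": KIND_SPHEROCYLINDER,
}

FULL_AREA = 4.0 * math.pi


class GeometryError(ValueError):
    """Invalid shape parameter or failed geometric computation."""


@dataclass(frozen=True)
class Body:
    """An area-normalized convex body of revolution.

    Attributes
    ----------
    shape_kind : str
        One of ``sphere``, ``prolate_spheroid``, ``spherocylinder``.
    param_a, param_c : float
        Shape scalars: radius for the sphere; (a, c) semi-axes for the
        spheroid; (cap radius, cylinder length) for the spherocylinder.
    """

    shape_kind: str
    param_a: float
    param_c: float = 0.0

    @property
    def kind_code(self) -> int:
        return _KIND_CODES[self.shape_kind]

    @property
    def surface_area(self) -> float:
        return FULL_AREA

    @property
    def max_half_extent(self) -> float:
        if self.shape_kind == "sphere":
            return self.param_a
        if self.shape_kind == "prolate_spheroid":
            return self.param_c
        return 0.5 * self.param_c + self.param_a

    @property
    def gamma(self) -> float:
        """Aspect ratio of the bounding dimensions (1 for the sphere)."""
        if self.shape_kind == "sphere":
            return 1.0
        if self.shape_kind == "prolate_spheroid":
            return self.param_c / self.param_a
        return self.max_half_extent / self.param_a

    # -- queries -----------------------------------------------------------

    def signed_distance(self, point) -> float:
        """Exact signed distance: > 0 outside, 0 on the surface, < 0 inside."""
        x, y, z = float(point[0]), float(point[1]), float(point[2])
        if self.shape_kind == "prolate_spheroid":
            sx, sy, sz, _, _, _ = _kernels.nearest_point(
                self.kind_code, self.param_a, self.param_c, x, y, z)
            d = math.hypot(math.hypot(x - sx, y - sy), z - sz)
            f = (x * x + y * y) / self.param_a ** 2 + z * z / self.param_c ** 2
            return d if f >= 1.0 else -d
        return _kernels.signed_distance_fast(
            self.kind_code, self.param_a, self.param_c, x, y, z)

    def distance_lower_bound(self, point) -> float:
        """Cheap certified bound used by the simulation hot loop (exact for
        sphere and spherocylinder; never overestimates for the spheroid)."""
        return _kernels.signed_distance_fast(
            self.kind_code, self.param_a, self.param_c,
            float(point[0]), float(point[1]), float(point[2]))

    def nearest_surface_point(self, point):
        """Return (surface point, outward unit normal) nearest to ``point``."""
        sx, sy, sz, nx, ny, nz = _kernels.nearest_point(
            self.kind_code, self.param_a, self.param_c,
            float(point[0]), float(point[1]), float(point[2]))
        return np.array([sx, sy, sz]), np.array([nx, ny, nz])

    def contains(self, point) -> bool:
        return self.signed_distance(point) < 0.0

    def reflect_into_layer(self, point, max_depth: float | None = None):
        """Specular image of an interior point across the tangent plane at
        its nearest surface point.

        Raises ``GeometryError`` if the penetration depth exceeds
        ``max_depth`` (when given): that signals a Brownian step too large
        for the local curvature.
        """
        p = np.asarray(point, dtype=float)
        s, n = self.nearest_surface_point(p)
        dot = float(np.dot(p - s, n))
        if dot > 1e-12:
            raise GeometryError("reflect_into_layer called with an exterior point")
        if max_depth is not None and -dot > max_depth:
            raise GeometryError(
                f"penetration depth {-dot:.3e} exceeds the boundary-layer "
                f"width {max_depth:.3e}; reduce the Brownian step")
        out = p - 2.0 * dot * n
        if self.signed_distance(out) < 0.0:
            out = s - dot * n
        return out

    # -- meridian profile --------------------------------------------------

    def profile_radius(self, z: float) -> float:
        """Cross-section radius rho(z) of the surface of revolution."""
        h = self.max_half_extent
        if abs(z) > h:
            return 0.0
        if self.shape_kind == "sphere":
            return math.sqrt(max(0.0, self.param_a ** 2 - z * z))
        if self.shape_kind == "prolate_spheroid":
            return self.param_a * math.sqrt(max(0.0, 1.0 - (z / self.param_c) ** 2))
        half_l = 0.5 * self.param_c
        if abs(z) <= half_l:
            return self.param_a
        return math.sqrt(max(0.0, self.param_a ** 2 - (abs(z) - half_l) ** 2))

    def area_density(self, z: float) -> float:
        """dA/dz of the surface of revolution at height z."""
        if self.shape_kind in ("sphere", "spherocylinder"):
            # Archimedes: both the spherical caps and the cylinder have
            # constant dA/dz = 2 pi r
            return 2.0 * math.pi * self.param_a
        a, c = self.param_a, self.param_c
        if abs(z) > c:
            return 0.0
        u = z / c
        return 2.0 * math.pi * math.sqrt(
            a * a * (1.0 - u * u) + (a * a / c) ** 2 * u * u)

    def quadrature_area(self, rtol: float = 1e-10) -> float:
        """Numeric surface area (independent check of the normalization)."""
        h = self.max_half_extent
        val, _ = integrate.quad(self.area_density, -h, h,
                                epsrel=rtol, epsabs=1e-12, limit=200)
        return val

    def to_dict(self) -> dict:
        return {"shape_kind": self.shape_kind,
                "param_a": self.param_a, "param_c": self.param_c}

    @classmethod
    def from_dict(cls, d: dict) -> "Body":
        return cls(d["shape_kind"], float(d["param_a"]), float(d["param_c"]))


def prolate_area(a: float, gamma: float) -> float:
    """Closed-form surface area of a prolate spheroid with semi-axes (a, a, gamma*a)."""
    if gamma == 1.0:
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - 1.0 / (gamma * gamma))
    return 2.0 * math.pi * a * a * (1.0 + gamma * math.asin(e) / e)


def make_body(shape_kind: str, parameter: float | None = None) -> Body:
    """Construct an area-normalized body.

    Parameters
    ----------
    shape_kind : str
        ``sphere`` (no parameter), ``prolate_spheroid`` (parameter = aspect
        ratio gamma >= 1) or ``spherocylinder`` (parameter = relative
        cylinder length L/r_c >= 0).
    """
    if shape_kind == "sphere":
        return Body("sphere", 1.0, 0.0)
    if shape_kind == "prolate_spheroid":
        if parameter is None:
            raise GeometryError("prolate_spheroid requires the aspect ratio gamma")
        gamma = float(parameter)
        if gamma < 1.0:
            raise GeometryError(f"aspect ratio gamma must be >= 1, got {gamma}")
        if gamma == 1.0:
            return Body("prolate_spheroid", 1.0, 1.0)
        # solve prolate_area(a, gamma) = 4 pi; area ~ a^2, closed form
        e = math.sqrt(1.0 - 1.0 / (gamma * gamma))
        a = math.sqrt(2.0 / (1.0 + gamma * math.asin(e) / e))
        return Body("prolate_spheroid", a, gamma * a)
    if shape_kind == "spherocylinder":
        if parameter is None:
            raise GeometryError("spherocylinder requires the relative length L/r_c")
        l_rel = float(parameter)
        if l_rel < 0.0:
            raise GeometryError(f"relative cylinder length must be >= 0, got {l_rel}")
        # 4 pi r^2 + 2 pi r L = 4 pi with L = l_rel * r
        r = math.sqrt(2.0 / (2.0 + l_rel))
        return Body("spherocylinder", r, l_rel * r)
    raise GeometryError(f"unknown shape kind {shape_kind!r}")


@dataclass(frozen=True)
class DomainPartition:
    """M equal-area surface bands stacked along the symmetry axis."""

    M: int
    band_edges: np.ndarray = field(repr=False)   # (M+1,) increasing z
    domain_areas: np.ndarray = field(repr=False)  # (M,)
    max_half_extent: float = 1.0

    @property
    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    @property
    def cos_beta(self) -> np.ndarray:
        """Band centres as a scaled axial coordinate z / z_max in (-1, 1)."""
        return self.band_centers / self.max_half_extent

    def domain_of(self, z: float) -> int:
        m = int(np.searchsorted(self.band_edges, z) - 1)
        return min(max(m, 0), self.M - 1)

    def to_dict(self) -> dict:
        return {"M": self.M,
                "band_edges": self.band_edges.tolist(),
                "domain_areas": self.domain_areas.tolist(),
                "max_half_extent": self.max_half_extent}

    @classmethod
    def from_dict(cls, d: dict) -> "DomainPartition":
        return cls(int(d["M"]), np.asarray(d["band_edges"], dtype=float),
                   np.asarray(d["domain_areas"], dtype=float),
                   float(d["max_half_extent"]))


def domain_partition(body: Body, M: int) -> DomainPartition:
    """Split the surface into M equal-area axial bands.

    Band edges invert the cumulative surface-area function along z.  For the
    sphere and the spherocylinder dA/dz is constant, so the edges are
    uniform in z; for the spheroid the cumulative area is integrated
    numerically and inverted with a bracketed root find.
    """
    if M < 1:
        raise GeometryError(f"M must be >= 1, got {M}")
    h = body.max_half_extent
    if body.shape_kind in ("sphere", "spherocylinder"):
        edges = np.linspace(-h, h, M + 1)
    else:
        def cum(z):
            val, _ = integrate.quad(body.area_density, -h, z,
                                    epsrel=1e-12, epsabs=1e-13, limit=200)
            return val

        total = cum(h)
        edges = np.empty(M + 1)
        edges[0] = -h
        edges[M] = h
        for m in range(1, M):
            target = total * m / M
            edges[m] = optimize.brentq(lambda z: cum(z) - target, -h, h,
                                       xtol=1e-14, rtol=8.9e-16)
    areas = np.empty(M)
    for m in range(M):
        val, _ = integrate.quad(body.area_density, edges[m], edges[m + 1],
                                epsrel=1e-12, epsabs=1e-13, limit=200)
        areas[m] = val
    # remove the O(1e-12) quadrature drift so the bands sum exactly to 4 pi
    areas *= FULL_AREA / areas.sum()
    return DomainPartition(M, edges, areas, h)


def partition_to_json(body: Body, partition: DomainPartition) -> str:
    return json.dumps({"body": body.to_dict(), "partition": partition.to_dict()},
                      indent=2)
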