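"""Numba-compiled inner loops of the reflective walk-on-spheres simulation.

Everything here works on scalars and flat arrays so that the per-particle
loop compiles to machine code.  Shapes are encoded as an integer kind plus
two scalar parameters:

* ``KIND_SPHERE``:         pa = radius R, pc unused
* ``KIND_SPHEROID``:       pa = equatorial semi-axis a, pc = polar semi-axis c (c >= a)
* ``KIND_SPHEROCYLINDER``: pa = cap radius r_c, pc = cylinder length L

The body is axisymmetric about z and mirror-symmetric about z = 0, with its
centroid at the origin.
"""

import math

import numpy as np
from numba import njit

KIND_SPHERE = 0
KIND_SPHEROID = 1
KIND_SPHEROCYLINDER = 2


@njit(cache=True)
def signed_distance_fast(kind, pa, pc, x, y, z):
    """Signed distance to the body surface: exact for sphere and
    spherocylinder; for the spheroid a certified lower bound on the distance
    magnitude that never overestimates and always has the exact sign."""
    if kind == KIND_SPHERE:
        return math.sqrt(x * x + y * y + z * z) - pa
    if kind == KIND_SPHEROCYLINDER:
        rho = math.sqrt(x * x + y * y)
        dz = abs(z) - 0.5 * pc
        if dz <= 0.0:
            return rho - pa
        return math.sqrt(rho * rho + dz * dz) - pa
    # prolate spheroid.  With T = diag(1/a,1/a,1/c) and F = |T p|,
    # |p - s| >= min(a,c) * | |T p| - 1 | for any surface point s, and the
    # body lies inside the ball of radius c, giving two lower bounds.
    a = pa
    c = pc
    F = math.sqrt((x * x + y * y) / (a * a) + (z * z) / (c * c))
    lb1 = a * (F - 1.0)
    lb2 = math.sqrt(x * x + y * y + z * z) - c
    return lb1 if lb1 > lb2 else lb2


@njit(cache=True)
def nearest_point(kind, pa, pc, x, y, z):
    """Nearest surface point and outward unit normal.

    Returns (sx, sy, sz, nx, ny, nz).  For the spheroid the meridian angle t
    (surface point (a sin t, c cos t) for rho, |z|) is found by bisection on
    the stationarity condition of the squared distance; the root is
    bracketed by construction on [0, pi/2].
    """
    if kind == KIND_SPHERE:
        r = math.sqrt(x * x + y * y + z * z)
        if r < 1e-300:
            return pa, 0.0, 0.0, 1.0, 0.0, 0.0
        inv = 1.0 / r
        return pa * x * inv, pa * y * inv, pa * z * inv, x * inv, y * inv, z * inv
    if kind == KIND_SPHEROCYLINDER:
        rc = pa
        half_l = 0.5 * pc
        rho = math.sqrt(x * x + y * y)
        if abs(z) <= half_l:
            if rho < 1e-300:
                return rc, 0.0, z, 1.0, 0.0, 0.0
            inv = 1.0 / rho
            return rc * x * inv, rc * y * inv, z, x * inv, y * inv, 0.0
        zc = half_l if z > 0.0 else -half_l
        dx = x
        dy = y
        dz = z - zc
        n = math.sqrt(dx * dx + dy * dy + dz * dz)
        if n < 1e-300:
            nz = 1.0 if z > 0.0 else -1.0
            return 0.0, 0.0, zc + rc * nz, 0.0, 0.0, nz
        inv = 1.0 / n
        ux = dx * inv
        uy = dy * inv
        uz = dz * inv
        return rc * ux, rc * uy, zc + rc * uz, ux, uy, uz
    # prolate spheroid
    a = pa
    c = pc
    rho = math.sqrt(x * x + y * y)
    zz = abs(z)
    lo = 0.0
    hi = 0.5 * math.pi
    # f(t) = -(rho - a sin t) a cos t + (zz - c cos t) c sin t,
    # f(0) = -a rho <= 0, f(pi/2) = c zz >= 0; f increases through the root.
    for _ in range(60):
        t = 0.5 * (lo + hi)
        st = math.sin(t)
        ct = math.cos(t)
        f = (zz - c * ct) * c * st - (rho - a * st) * a * ct
        if f > 0.0:
            hi = t
        else:
            lo = t
    t = 0.5 * (lo + hi)
    st = math.sin(t)
    ct = math.cos(t)
    srho = a * st
    sz = c * ct
    if z < 0.0:
        sz = -sz
    if rho < 1e-300:
        cphi = 1.0
        sphi = 0.0
    else:
        cphi = x / rho
        sphi = y / rho
    # outward normal along grad[(rho/a)^2 + (z/c)^2]
    nrho = st / a
    nz = ct / c
    if z < 0.0:
        nz = -nz
    nn = math.sqrt(nrho * nrho + nz * nz)
    nrho /= nn
    nz /= nn
    return srho * cphi, srho * sphi, sz, nrho * cphi, nrho * sphi, nz


@njit(cache=True)
def _rand_unit():
    # rejection sampling of an isotropic direction
    while True:
        ux = 2.0 * np.random.random() - 1.0
        uy = 2.0 * np.random.random() - 1.0
        uz = 2.0 * np.random.random() - 1.0
        s = ux * ux + uy * uy + uz * uz
        if 1e-12 < s <= 1.0:
            inv = 1.0 / math.sqrt(s)
            return ux * inv, uy * inv, uz * inv


@njit(cache=True)
def sample_return_mu(r, rb, u):
    """Inverse-CDF sample of mu = cos(angle) of the first-passage landing
    point on the sphere |p| = rb, as seen from an exterior point at radius r,
    conditioned on return.  Density f(mu) ~ (r^2-rb^2)/(r^2+rb^2-2 r rb mu)^{3/2}."""
    w = 2.0 * rb * u / (r * r - rb * rb) + 1.0 / (r + rb)
    mu = (r * r + rb * rb - 1.0 / (w * w)) / (2.0 * r * rb)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=True)
def run_block(kind, pa, pc, edges, rb, lam, d_star, delta,
              n_particles, seed, use_point, px0, py0, pz0,
              pstar, gaussian_steps, max_events, max_steps):
    """Simulate one block of reflected random walkers and tally transitions.

    States: 0 = start, 1..M = reflection in surface domain m, M+1 = escape.
    ``pstar`` has shape (n_profiles, M); for each profile an online
    ("pay-now") absorption coin is flipped at every reflection event until
    the particle is first absorbed under that profile.  Pass shape (0, M)
    to disable.

    Returns (counts, online, n_capped, n_bad_reflect) where ``counts`` is
    the (M+2, M+2) transition tally over completed particles, ``online`` the
    (n_profiles, M) tally of first online absorptions by domain.  Particles
    exceeding ``max_steps`` or ``max_events`` are excluded entirely and
    counted in ``n_capped``.
    """
    np.random.seed(seed)
    M = edges.shape[0] - 1
    nprof = pstar.shape[0]
    counts = np.zeros((M + 2, M + 2), dtype=np.int64)
    online = np.zeros((nprof, M), dtype=np.int64)
    ev_from = np.empty(max_events, dtype=np.int64)
    ev_to = np.empty(max_events, dtype=np.int64)
    absorbed_dom = np.empty(max(nprof, 1), dtype=np.int64)
    n_capped = 0
    n_bad = 0
    sig = lam / math.sqrt(2.0)  # per-coordinate std for Gaussian substeps
    rb2 = rb * rb * (1.0 + 1e-12)
    for _p in range(n_particles):
        if use_point:
            x = px0
            y = py0
            z = pz0
        else:
            cz = 2.0 * np.random.random() - 1.0
            ph = 2.0 * math.pi * np.random.random()
            s_ = math.sqrt(max(0.0, 1.0 - cz * cz))
            x = rb * s_ * math.cos(ph)
            y = rb * s_ * math.sin(ph)
            z = rb * cz
        state = 0
        nev = 0
        for q in range(nprof):
            absorbed_dom[q] = -1
        steps = 0
        completed = False
        while True:
            steps += 1
            if steps > max_steps or nev >= max_events - 1:
                n_capped += 1
                break
            r2 = x * x + y * y + z * z
            if r2 > rb2:
                r = math.sqrt(r2)
                if np.random.random() * r > rb:
                    ev_from[nev] = state
                    ev_to[nev] = M + 1
                    nev += 1
                    completed = True
                    break
                mu = sample_return_mu(r, rb, np.random.random())
                invr = 1.0 / r
                ax = x * invr
                ay = y * invr
                az = z * invr
                # orthonormal frame (e1, e2) perpendicular to the axis a
                if abs(ax) < 0.9:
                    vx, vy, vz = 1.0, 0.0, 0.0
                else:
                    vx, vy, vz = 0.0, 1.0, 0.0
                d_ = vx * ax + vy * ay + vz * az
                e1x = vx - d_ * ax
                e1y = vy - d_ * ay
                e1z = vz - d_ * az
                inv1 = 1.0 / math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x *= inv1
                e1y *= inv1
                e1z *= inv1
                e2x = ay * e1z - az * e1y
                e2y = az * e1x - ax * e1z
                e2z = ax * e1y - ay * e1x
                psi = 2.0 * math.pi * np.random.random()
                s_ = math.sqrt(max(0.0, 1.0 - mu * mu))
                cx = s_ * math.cos(psi)
                sx_ = s_ * math.sin(psi)
                x = rb * (mu * ax + cx * e1x + sx_ * e2x)
                y = rb * (mu * ay + cx * e1y + sx_ * e2y)
                z = rb * (mu * az + cx * e1z + sx_ * e2z)
                continue
            d = signed_distance_fast(kind, pa, pc, x, y, z)
            if d > d_star:
                # walk-on-spheres jump, shrunk by the safety margin delta
                rad = d - delta
                ux, uy, uz = _rand_unit()
                x += rad * ux
                y += rad * uy
                z += rad * uz
                continue
            # finite-step Brownian substep inside the boundary layer
            if gaussian_steps:
                qx = x + sig * np.random.normal(0.0, 1.0)
                qy = y + sig * np.random.normal(0.0, 1.0)
                qz = z + sig * np.random.normal(0.0, 1.0)
            else:
                ux, uy, uz = _rand_unit()
                qx = x + lam * ux
                qy = y + lam * uy
                qz = z + lam * uz
            if signed_distance_fast(kind, pa, pc, qx, qy, qz) < 0.0:
                # reflection event
                sx, sy, sz, nx, ny, nz = nearest_point(kind, pa, pc, qx, qy, qz)
                dot = (qx - sx) * nx + (qy - sy) * ny + (qz - sz) * nz
                if -dot > d_star:
                    n_bad += 1
                m = np.searchsorted(edges, sz) - 1
                if m < 0:
                    m = 0
                elif m >= M:
                    m = M - 1
                ev_from[nev] = state
                ev_to[nev] = m + 1
                nev += 1
                for q in range(nprof):
                    if absorbed_dom[q] < 0:
                        if np.random.random() < pstar[q, m]:
                            absorbed_dom[q] = m
                state = m + 1
                # specular image across the local tangent plane
                rx = qx - 2.0 * dot * nx
                ry = qy - 2.0 * dot * ny
                rz = qz - 2.0 * dot * nz
                if signed_distance_fast(kind, pa, pc, rx, ry, rz) < 0.0:
                    # curvature pushed the image back inside; place it on the
                    # outward normal at the same depth (always exterior for a
                    # convex body)
                    rx = sx - dot * nx
                    ry = sy - dot * ny
                    rz = sz - dot * nz
                x = rx
                y = ry
                z = rz
            else:
                x = qx
                y = qy
                z = qz
        if completed:
            for e in range(nev):
                counts[ev_from[e], ev_to[e]] += 1
            for q in range(nprof):
                if absorbed_dom[q] >= 0:
                    online[q, absorbed_dom[q]] += 1
    return counts, online, n_capped, n_bad
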