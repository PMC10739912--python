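import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from robinflux import GeometryError, domain_partition, make_body
from robinflux.geometry import prolate_area

FOUR_PI = 4.0 * math.pi


def _meridian_brute_distance(body, point, n=200_001):
    """Independent oracle: dense scan of the meridian profile."""
    rho = math.hypot(point[0], point[1])
    z = point[2]
    h = body.max_half_extent
    zs = np.linspace(-h, h, n)
    rs = np.array([body.profile_radius(zz) for zz in zs])
    d = np.sqrt((rho - rs) ** 2 + (z - zs) ** 2)
    return d.min()


class TestMakeBody:
    @pytest.mark.parametrize("kind,param", [
        ("sphere", None),
        ("prolate_spheroid", 1.0),
        ("prolate_spheroid", 3.0),
        ("prolate_spheroid", 10.0),
        ("spherocylinder", 0.0),
        ("spherocylinder", 2.0),
        ("spherocylinder", 8.0),
    ])
    def test_area_normalized_to_reference_sphere(self, kind, param):
        body = make_body(kind, param)
        assert body.quadrature_area() == pytest.approx(FOUR_PI, abs=1e-6)

    def test_sphere_is_unit(self):
        assert make_body("sphere").param_a == 1.0

    def test_degenerate_spheroid_is_unit_sphere(self):
        body = make_body("prolate_spheroid", 1.0)
        assert body.param_a == pytest.approx(1.0, abs=1e-12)
        assert body.param_c == pytest.approx(1.0, abs=1e-12)

    def test_gamma3_semi_axes_match_area_solve(self):
        # independent root-find of the closed-form prolate area
        a_ref = optimize.brentq(lambda a: prolate_area(a, 3.0) - FOUR_PI,
                                0.1, 1.0, xtol=1e-14)
        body = make_body("prolate_spheroid", 3.0)
        assert body.param_a == pytest.approx(a_ref, rel=1e-12)
        assert body.param_a == pytest.approx(0.6378, abs=5e-5)
        assert body.param_c == pytest.approx(1.9134, abs=1e-4)
        assert body.param_c / body.param_a == 3.0

    def test_spherocylinder_area_closed_form(self):
        body = make_body("spherocylinder", 2.0)
        r, length = body.param_a, body.param_c
        assert length / r == pytest.approx(2.0, rel=1e-12)
        assert 4 * math.pi * r ** 2 + 2 * math.pi * r * length == pytest.approx(
            FOUR_PI, rel=1e-12)

    @pytest.mark.parametrize("kind,param", [
        ("prolate_spheroid", 0.5),
        ("spherocylinder", -1.0),
        ("prolate_spheroid", None),
        ("unknown_shape", 1.0),
    ])
    def test_invalid_parameters_raise(self, kind, param):
        with pytest.raises(GeometryError):
            make_body(kind, param)


class TestSignedDistance:
    def test_sphere_axis_point(self, sphere_body):
        assert sphere_body.signed_distance((0, 0, 2)) == pytest.approx(1.0)
        assert sphere_body.signed_distance((0, 0, 0.5)) == pytest.approx(-0.5)

    def test_spheroid_pole_distance(self, spheroid_body):
        d = spheroid_body.signed_distance((0, 0, 2.0))
        assert d == pytest.approx(2.0 - spheroid_body.param_c, abs=1e-9)

    def test_spherocylinder_side_and_cap(self, spherocylinder_body):
        r, length = spherocylinder_body.param_a, spherocylinder_body.param_c
        assert spherocylinder_body.signed_distance((2 * r, 0, 0)) == pytest.approx(r)
        tip = length / 2 + r
        assert spherocylinder_body.signed_distance((0, 0, tip + 0.3)) == pytest.approx(0.3)

    @pytest.mark.parametrize("body_name", ["sphere_body", "spheroid_body",
                                           "spherocylinder_body"])
    def test_surface_points_have_zero_distance(self, body_name, request, rng):
        body = request.getfixturevalue(body_name)
        for _ in range(50):
            p = rng.normal(size=3) * 2
            s, _ = body.nearest_surface_point(p)
            assert abs(body.signed_distance(s)) < 1e-9

    @pytest.mark.parametrize("body_name", ["spheroid_body", "spherocylinder_body"])
    def test_exact_distance_matches_meridian_scan(self, body_name, request, rng):
        body = request.getfixturevalue(body_name)
        for _ in range(12):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = u * body.max_half_extent * rng.uniform(0.9, 1.6)
            d = body.signed_distance(p)
            assert abs(d) == pytest.approx(_meridian_brute_distance(body, p),
                                           abs=1e-6)

    def test_lower_bound_never_overestimates(self, spheroid_body, rng):
        for _ in range(200):
            p = rng.normal(size=3) * 1.5
            lb = spheroid_body.distance_lower_bound(p)
            exact = spheroid_body.signed_distance(p)
            if exact >= 0:
                assert lb <= exact + 1e-12
                assert (lb >= 0) == (exact >= 0)


class TestNearestSurfacePoint:
    def test_sphere_axis(self, sphere_body):
        s, n = sphere_body.nearest_surface_point((0, 0, 2))
        assert np.allclose(s, [0, 0, 1], atol=1e-12)
        assert np.allclose(n, [0, 0, 1], atol=1e-12)

    def test_spheroid_on_axis_maps_to_pole(self, spheroid_body):
        s, n = spheroid_body.nearest_surface_point((0, 0, 2.5))
        assert np.allclose(s, [0, 0, spheroid_body.param_c], atol=1e-9)
        assert np.allclose(n, [0, 0, 1], atol=1e-9)

    @pytest.mark.parametrize("body_name", ["sphere_body", "spheroid_body",
                                           "spherocylinder_body"])
    def test_normal_alignment_near_surface(self, body_name, request, rng):
        """(point - surface point) must be parallel to the outward normal."""
        body = request.getfixturevalue(body_name)
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            q = u * body.max_half_extent * rng.uniform(0.95, 1.1)
            s, n = body.nearest_surface_point(q)
            v = np.asarray(q) - s
            nv = np.linalg.norm(v)
            if nv < 1e-9:
                continue
            assert np.linalg.norm(np.cross(v / nv, n)) < 1e-6
            assert abs(np.linalg.norm(n) - 1.0) < 1e-12


class TestDomainPartition:
    def test_sphere_edges_uniform_in_z(self, sphere_body):
        part = domain_partition(sphere_body, 2)
        assert np.allclose(part.band_edges, [-1, 0, 1])
        assert np.allclose(part.domain_areas, [2 * math.pi, 2 * math.pi])
        part4 = domain_partition(sphere_body, 4)
        assert np.allclose(part4.band_edges, [-1, -0.5, 0, 0.5, 1])

    @pytest.mark.parametrize("body_name,M", [
        ("spheroid_body", 32), ("spherocylinder_body", 16),
    ])
    def test_equal_areas(self, body_name, M, request):
        body = request.getfixturevalue(body_name)
        part = domain_partition(body, M)
        assert np.ptp(part.domain_areas) < 1e-8
        assert part.domain_areas.sum() == pytest.approx(FOUR_PI, rel=1e-12)
        assert part.band_edges[0] == -body.max_half_extent
        assert part.band_edges[-1] == body.max_half_extent

    def test_refinement_consistency(self, spheroid_body):
        """Merging adjacent bands of a 2M partition reproduces the M bands."""
        p8 = domain_partition(spheroid_body, 8)
        p16 = domain_partition(spheroid_body, 16)
        merged = p16.domain_areas.reshape(8, 2).sum(axis=1)
        assert np.allclose(merged, p8.domain_areas, atol=1e-10)
        assert np.allclose(p16.band_edges[::2], p8.band_edges, atol=1e-10)

    def test_domain_of_band_centers(self, spheroid_body):
        part = domain_partition(spheroid_body, 12)
        for m, z in enumerate(part.band_centers):
            assert part.domain_of(z) == m
        assert part.domain_of(-10.0) == 0
        assert part.domain_of(10.0) == 11

    def test_invalid_M(self, sphere_body):
        with pytest.raises(GeometryError):
            domain_partition(sphere_body, 0)


class TestReflectIntoLayer:
    def test_sphere_radial_mirror(self, sphere_body):
        eps = 1e-3
        p = np.array([0.0, 0.0, 1.0 - eps])
        out = sphere_body.reflect_into_layer(p)
        assert np.linalg.norm(out) == pytest.approx(1.0 + eps, abs=1e-12)
        assert np.allclose(out / np.linalg.norm(out), [0, 0, 1])

    def test_surface_point_unchanged(self, sphere_body):
        p = np.array([0.0, 1.0, 0.0])
        out = sphere_body.reflect_into_layer(p)
        assert np.allclose(out, p, atol=1e-12)

    def test_spheroid_near_pole_depth_preserved(self, spheroid_body):
        eps = 1e-3
        c = spheroid_body.param_c
        p = np.array([1e-4, 0.0, c - eps])
        out = spheroid_body.reflect_into_layer(p)
        d_out = spheroid_body.signed_distance(out)
        assert d_out > 0
        # depth preserved up to a curvature correction O(eps^2 / radius)
        assert d_out == pytest.approx(-spheroid_body.signed_distance(p),
                                      abs=50 * eps ** 2)

    def test_exterior_point_rejected(self, sphere_body):
        with pytest.raises(GeometryError):
            sphere_body.reflect_into_layer(np.array([0.0, 0.0, 1.5]))

    def test_too_deep_rejected(self, sphere_body):
        with pytest.raises(GeometryError, match="penetration"):
            sphere_body.reflect_into_layer(np.array([0.0, 0.0, 0.5]),
                                           max_depth=0.01)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(gamma=st.floats(1.0, 12.0),
       ct=st.floats(-0.999, 0.999),
       phi=st.floats(0.0, 2 * math.pi),
       scale=st.floats(1.0001, 3.0))
def test_spheroid_exterior_points_classified_consistently(gamma, ct, phi, scale):
    """Scaling a surface point outward always yields positive distance and a
    nearest point whose distance the cheap bound never overestimates."""
    body = make_body("prolate_spheroid", gamma)
    a, c = body.param_a, body.param_c
    stn = math.sqrt(1 - ct * ct)
    surf = np.array([a * stn * math.cos(phi), a * stn * math.sin(phi), c * ct])
    p = surf * scale
    d = body.signed_distance(p)
    assert d > 0
    assert body.distance_lower_bound(p) <= d + 1e-12
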