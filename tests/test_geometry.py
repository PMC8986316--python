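"""Geometry primitives: containment, crossings, normals, transport
distances, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from polargrad import geometry as geo
from polargrad.geometry import CellGeometry


SPHERE = CellGeometry.sphere(10)
CYLINDER = CellGeometry.cylinder(10, 30)
SPHEROID = CellGeometry.spheroid(10, 20)
SHAPES = [SPHERE, CYLINDER, SPHEROID]


def random_interior(g, n, seed=0):
    return geo.sample_uniform_interior(g, n, np.random.default_rng(seed))


class TestContainsAndSections:
    @pytest.mark.parametrize(
        "g, p, expected",
        [
            (SPHERE, (0, 0, 9.9), True),
            (SPHERE, (0, 0, 10.1), False),
            (SPHEROID, (0, 10 * np.sqrt(0.75) + 0.01, 10), False),
            (CYLINDER, (9.9, 0, 29.9), True),
            (CYLINDER, (0, 0, 30.1), False),
        ],
    )
    def test_examples(self, g, p, expected):
        assert geo.contains(g, np.array(p, float)) is expected

    @pytest.mark.parametrize(
        "g, z, expected",
        [
            (SPHERE, 0.0, 10.0),
            (SPHERE, 10.0, 0.0),
            (SPHEROID, 10.0, 10 * np.sqrt(0.75)),
            (CYLINDER, -15.0, 10.0),
        ],
    )
    def test_cross_section_radius(self, g, z, expected):
        assert geo.cross_section_radius(g, z) == pytest.approx(expected, abs=1e-12)

    def test_cross_section_outside_errors(self):
        with pytest.raises(ValueError):
            geo.cross_section_radius(SPHERE, 10.5)


class TestBoundaryCrossing:
    @pytest.mark.parametrize(
        "g, p_in, p_out, expected",
        [
            (SPHERE, (0, 0, 0), (0, 0, 20), (0, 0, 10)),
            (CYLINDER, (9, 0, 0), (11, 0, 0), (10, 0, 0)),
            (SPHEROID, (0, 0, 19), (0, 0, 21), (0, 0, 20)),
            (CYLINDER, (0, 0, 29), (0, 0, 31), (0, 0, 30)),
        ],
    )
    def test_examples(self, g, p_in, p_out, expected):
        s = geo.boundary_crossing(g, np.array(p_in, float), np.array(p_out, float))
        assert np.allclose(s, expected, atol=1e-9)

    def test_violated_precondition_errors(self):
        with pytest.raises(ValueError):
            geo.boundary_crossing(SPHERE, np.array([0.0, 0, 0]), np.array([0.0, 0, 5]))

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(
        shape_idx=st.integers(0, 2),
        seed=st.integers(0, 10_000),
    )
    def test_crossing_lies_on_surface(self, shape_idx, seed):
        """The crossing point satisfies the implicit surface equation to
        1e-9 relative tolerance and lies on the segment."""
        g = SHAPES[shape_idx]
        rng = np.random.default_rng(seed)
        p_in = geo.sample_uniform_interior(g, 1, rng)[0]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        p_out = p_in + direction * 4 * (g.polar_extent + g.R)
        if geo.contains(g, p_out):  # pragma: no cover - cannot happen
            return
        s = geo.boundary_crossing(g, p_in, p_out)
        if g.shape == "cylinder":
            res = min(
                abs(np.hypot(s[0], s[1]) - g.R) / g.R,
                abs(abs(s[2]) - g.L) / g.L,
            )
        else:
            az = g.a if g.shape == "spheroid" else g.R
            res = abs((s[0] ** 2 + s[1] ** 2) / g.R**2 + s[2] ** 2 / az**2 - 1.0)
        assert res < 1e-9
        t = np.dot(s - p_in, direction)
        assert -1e-9 <= t <= np.linalg.norm(p_out - p_in) + 1e-9


class TestNormals:
    @pytest.mark.parametrize(
        "g, s, expected",
        [
            (SPHERE, (0, 0, 10), (0, 0, -1)),
            (CYLINDER, (10, 0, 5), (-1, 0, 0)),
            (CYLINDER, (3, 0, 30), (0, 0, -1)),
            (SPHEROID, (10, 0, 0), (-1, 0, 0)),
        ],
    )
    def test_examples(self, g, s, expected):
        n = geo.inward_normal(g, np.array(s, float))
        assert np.allclose(n, expected, atol=1e-9)

    def test_off_surface_errors(self):
        with pytest.raises(ValueError):
            geo.inward_normal(SPHERE, np.array([0.0, 0, 5]))

    def test_normal_points_inward(self):
        for g in SHAPES:
            pts = random_interior(g, 50, seed=3)
            s = geo.project_to_surface(g, pts)
            n = geo.inward_normal(g, s)
            assert np.all(geo.contains(g, s + 1e-6 * g.polar_extent * n))


class TestTransportDistance:
    def test_sphere_equator(self):
        d = geo.arc_to_anterior_pole(SPHERE, np.array([10.0, 0, 0]))
        assert d == pytest.approx(np.pi * 10 / 2, abs=1e-6)

    def test_cylinder_lateral_posterior_end(self):
        d = geo.arc_to_anterior_pole(CYLINDER, np.array([10.0, 0, -30.0]))
        assert d == pytest.approx(60.0, abs=1e-9)

    def test_cylinder_caps(self):
        d_ant = geo.arc_to_anterior_pole(CYLINDER, np.array([3.0, 0, 30.0]))
        assert d_ant == pytest.approx(3.0, abs=1e-9)
        d_post = geo.arc_to_anterior_pole(CYLINDER, np.array([3.0, 0, -30.0]))
        assert d_post == pytest.approx((10 - 3) + 60, abs=1e-9)

    def test_round_spheroid_equals_sphere_formula(self):
        g = CellGeometry.spheroid(10, 10)
        d = geo.arc_to_anterior_pole(g, np.array([10.0, 0, 0]))
        assert d == pytest.approx(np.pi * 10 / 2, rel=1e-12)

    @pytest.mark.parametrize("a", [10.0, 20.0, 40.0])
    def test_spheroid_elliptic_vs_quadrature(self, a):
        """The elliptic-integral arc agrees with direct quadrature of
        the meridian arc length to 1e-6 relative error."""
        g = CellGeometry.spheroid(10, a)
        for zc in (-0.8 * a, -0.3 * a, 0.0, 0.4 * a, 0.9 * a):
            rho = geo.cross_section_radius(g, zc)
            s = np.array([rho, 0.0, zc])
            d = geo.arc_to_anterior_pole(g, s)
            phi0 = np.arcsin(zc / a)
            integrand = lambda p: np.hypot(10 * np.sin(p), a * np.cos(p))
            ref, _ = integrate.quad(integrand, phi0, np.pi / 2, limit=200)
            assert d == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("g", SHAPES, ids=lambda g: g.shape)
    def test_monotone_decreasing_to_pole(self, g):
        """d decreases along the meridian toward the anterior pole and
        vanishes there."""
        ext = g.polar_extent
        zs = np.linspace(-0.99 * ext, 0.99 * ext, 40)
        pts = np.column_stack(
            [geo.cross_section_radius(g, zs), np.zeros_like(zs), zs]
        )
        d = geo.arc_to_anterior_pole(g, pts)
        assert np.all(np.diff(d) < 0)
        pole = g.anterior_pole
        assert geo.arc_to_anterior_pole(g, pole) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("g", SHAPES, ids=lambda g: g.shape)
    def test_meridian_point_roundtrip(self, g):
        """arc → point → arc round-trips along the transport path."""
        ext = g.polar_extent
        zs = np.linspace(-0.95 * ext, 0.95 * ext, 11)
        pts = np.column_stack(
            [geo.cross_section_radius(g, zs), np.zeros_like(zs), zs]
        )
        d = np.atleast_1d(geo.arc_to_anterior_pole(g, pts))
        patch = geo.classify_surface(g, pts)
        back = geo.meridian_point_at_arc(g, d, np.zeros_like(d), patch)
        d2 = np.atleast_1d(geo.arc_to_anterior_pole(g, back))
        assert np.allclose(d, d2, rtol=1e-6, atol=1e-6)


class TestReleaseVolumeSampling:
    @pytest.mark.parametrize(
        "g, expected",
        [
            (CellGeometry.sphere(10, 0.5), (0, 0, 9.5)),
            (CellGeometry.cylinder(10, 30, 1.5), (0, 0, 28.5)),
            (CellGeometry.spheroid(10, 20, 1.0), (0, 0, 19.0)),
        ],
    )
    def test_release_point(self, g, expected):
        r0 = geo.release_point(g)
        assert np.allclose(r0, expected)
        assert geo.contains(g, r0)

    def test_default_epsilon_scales_with_polar_extent(self):
        assert SPHERE.epsilon == pytest.approx(0.5)
        assert CYLINDER.epsilon == pytest.approx(1.5)
        assert SPHEROID.epsilon == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "g, expected",
        [
            (SPHERE, 4188.7902),
            (CYLINDER, 18849.5559),
            (SPHEROID, 8377.5804),
        ],
    )
    def test_volume(self, g, expected):
        assert geo.volume(g) == pytest.approx(expected, rel=1e-6)

    def test_sample_empty(self):
        assert geo.sample_uniform_interior(SPHERE, 0, np.random.default_rng(0)).shape == (0, 3)

    def test_sample_symmetry_and_radial_law(self):
        pts = random_interior(SPHERE, 100_000, seed=5)
        assert np.all(geo.contains(SPHERE, pts))
        # mean z is 0 by symmetry; std of the mean ≈ R/2/sqrt(n)
        assert abs(pts[:, 2].mean()) < 0.1
        frac = np.mean(np.linalg.norm(pts, axis=1) < 5.0)
        assert frac == pytest.approx(1 / 8, abs=4 * np.sqrt(0.125 * 0.875 / 1e5))

    @pytest.mark.parametrize("g", SHAPES, ids=lambda g: g.shape)
    def test_sample_uniformity_chisquare(self, g):
        """Counts in 20 equal-volume axial slices are uniform (α=0.01)."""
        n = 100_000
        pts = random_interior(g, n, seed=7)
        ext = g.polar_extent
        # equal-volume slice edges from the inverse volume CDF
        zf = np.linspace(-ext, ext, 4001)
        if g.shape == "cylinder":
            cdf = (zf + ext) / (2 * ext)
        else:
            az = ext
            cdf = (zf * (1 - zf**2 / (3 * az**2)) + az * 2 / 3) / (4 * az / 3)
        edges = np.interp(np.linspace(0, 1, 21), cdf, zf)
        counts, _ = np.histogram(pts[:, 2], bins=edges)
        assert stats.chisquare(counts).pvalue > 0.01


class TestSurfaceDistance:
    def test_sphere_and_cylinder_exact(self):
        assert geo.surface_distance(SPHERE, np.array([0.0, 0, 7])) == pytest.approx(3.0)
        assert geo.surface_distance(CYLINDER, np.array([8.0, 0, 29])) == pytest.approx(1.0)

    def test_spheroid_estimate_near_surface(self):
        g = SPHEROID
        pts = random_interior(g, 200, seed=1)
        s = geo.project_to_surface(g, pts)
        probe = s + 0.05 * geo.inward_normal(g, s)
        d = geo.surface_distance(g, probe)
        assert np.all(d > 0)
        assert np.allclose(d, 0.05, rtol=0.3)
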