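"""Particle simulator: step statistics, wall handling, surface
transport, detachment, conservation, determinism, and consistency with
the independent solvers."""

import math

import numpy as np
import pytest
from scipy import stats

from polargrad import geometry as geo
from polargrad import oracle, profiles
from polargrad.analytic import SphereSolution
from polargrad.brownian import (
    ParticleSystem,
    SimConfig,
    capture_probability,
    diffusion_step,
    handle_wall,
    init_particles,
    run,
    surface_step,
)
from polargrad.geometry import CellGeometry

G10 = CellGeometry.sphere(10)


class TestConfig:
    def test_defaults_are_standard_conditions(self):
        cfg = SimConfig()
        assert (cfg.D, cfg.v, cfg.dt, cfg.N) == (1.0, 1.0, 1e-3, 1000)
        assert math.isinf(cfg.kon) and math.isinf(cfg.t_bound)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"D": 0.0},
            {"dt": -1e-3},
            {"N": 0},
            {"kon": -0.1},
            {"n_bins": 5},
            {"T_total": 10.0, "burn_in": 20.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_run_requires_recording_window(self):
        with pytest.raises(ValueError):
            run(SimConfig(T_total=1.0, burn_in=None), G10)  # auto burn-in too long


class TestCaptureProbability:
    def test_perfect_absorption_is_one(self):
        assert capture_probability(SimConfig()) == 1.0

    def test_reflecting_is_zero(self):
        assert capture_probability(SimConfig(kon=0.0)) == 0.0

    def test_reactive_formula_value(self):
        """P = kon·sqrt(π·Δt/D) = 0.0056050 for kon=0.1, D=1, Δt=1e-3."""
        cfg = SimConfig(kon=0.1)
        assert capture_probability(cfg) == pytest.approx(
            0.1 * math.sqrt(math.pi * 1e-3), rel=1e-12
        )
        assert capture_probability(cfg) == pytest.approx(5.605e-3, abs=1e-6)

    def test_clamped_to_one(self):
        assert capture_probability(SimConfig(kon=1e4)) == 1.0


class TestDiffusionStep:
    def test_msd_matches_free_brownian_motion(self):
        """⟨|Δr|²⟩ after n steps equals 6·D·n·Δt within 3σ."""
        cfg = SimConfig(D=1.0, dt=1e-3)
        rng = np.random.default_rng(0)
        pos = np.zeros((10_000, 3))
        n = 50
        for _ in range(n):
            pos = diffusion_step(pos, cfg, rng)
        msd = np.sum(pos**2, axis=1)
        expected = 6 * cfg.D * n * cfg.dt
        sem = msd.std() / math.sqrt(len(msd))
        assert abs(msd.mean() - expected) < 3 * sem

    def test_increment_distribution_gaussian_with_variance_2Ddt(self):
        cfg = SimConfig(D=1.0, dt=1e-3)
        rng = np.random.default_rng(1)
        inc = diffusion_step(np.zeros((100_000, 3)), cfg, rng)
        for axis in range(3):
            x = inc[:, axis]
            assert stats.normaltest(x).pvalue > 0.01
            # variance test: chi2 interval at alpha = 0.01
            ratio = x.var() / (2 * cfg.D * cfg.dt)
            n = len(x)
            lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1) / (n - 1)
            assert lo < ratio < hi


class TestHandleWall:
    def test_perfect_absorption_captures_at_crossing(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        p_old = np.array([[0.0, 0.0, 9.9]])
        p_prop = np.array([[0.0, 0.0, 10.3]])
        new_pos, captured, pts = handle_wall(G10, cfg, p_old, p_prop, rng)
        assert captured[0]
        assert np.allclose(pts[0], [0, 0, 10])

    def test_capture_at_equator_transit_time(self):
        """Capture at the equator → transit time πR/2 / v ≈ 15.708 s."""
        cfg = SimConfig(v=1.0)
        ps = init_particles(SimConfig(N=1), G10, np.random.default_rng(0))
        from polargrad.brownian import _capture

        _capture(ps, cfg, G10, np.array([0]), np.array([[10.0, 0.0, 0.0]]))
        assert ps.on_surface[0]
        assert ps.transit_remaining[0] == pytest.approx(math.pi * 10 / 2, rel=1e-9)

    def test_reflecting_wall_keeps_all_particles_inside(self):
        """kon = 0: nothing is ever captured and the cytoplasmic count
        stays N through many wall collisions."""
        cfg = SimConfig(kon=0.0, N=200, T_total=2.0, burn_in=0.5, seed=3)
        res = run(cfg, G10)
        assert res.wall_stats.captures == 0
        assert all(nc == 200 and ns == 0 for _, nc, ns in res.audit) or res.audit == []
        assert res.surface_fraction == 0.0

    def test_reflected_positions_inside(self):
        cfg = SimConfig(kon=0.0)
        rng = np.random.default_rng(4)
        p_old = geo.sample_uniform_interior(G10, 500, rng) * 0.999
        # push proposals outward beyond the surface
        p_prop = p_old * (10.5 / np.linalg.norm(p_old, axis=1, keepdims=True))
        new_pos, captured, _ = handle_wall(G10, cfg, p_old, p_prop, rng)
        assert not captured.any()
        assert np.all(geo.contains(G10, new_pos))


class TestSurfaceStep:
    def _bound_system(self, n, transit, cfg):
        ps = init_particles(SimConfig(N=n), G10, np.random.default_rng(0))
        ps.on_surface[:] = True
        ps.transit_remaining[:] = transit
        ps.transit_total[:] = transit
        ps.azimuth[:] = 0.0
        return ps

    def test_release_at_r0_without_detachment(self):
        cfg = SimConfig()
        ps = self._bound_system(5, 3 * cfg.dt, cfg)
        rng = np.random.default_rng(0)
        released = 0
        for _ in range(4):
            released += surface_step(ps, cfg, G10, rng)
        assert released == 5
        assert np.all(~ps.on_surface)
        assert np.allclose(ps.positions, geo.release_point(G10))

    def test_detachment_fraction_matches_exponential_waiting_time(self):
        """With transit 5 s and t_bound 1 s, the fraction detaching
        before delivery is 1 − e⁻⁵ (within 3σ at N = 10⁴)."""
        cfg = SimConfig(t_bound=1.0)
        n = 10_000
        ps = self._bound_system(n, 5.0, cfg)
        rng = np.random.default_rng(5)
        delivered = 0
        for _ in range(5001):
            delivered += surface_step(ps, cfg, G10, rng)
        p_detach = 1 - (1 - cfg.dt / cfg.t_bound) ** 5000
        expected = 1 - math.exp(-5.0)
        assert p_detach == pytest.approx(expected, rel=2e-3)
        frac = 1 - delivered / n
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma

    def test_detached_particles_reenter_cytoplasm_inside(self):
        cfg = SimConfig(t_bound=1e-9)  # detach immediately
        ps = self._bound_system(100, 5.0, cfg)
        rng = np.random.default_rng(6)
        surface_step(ps, cfg, G10, rng)
        assert np.all(~ps.on_surface)
        assert np.all(geo.contains(G10, ps.positions))


class TestRun:
    def test_conservation_and_flux_balance(self, sphere_sim_R10):
        """Particle number is conserved exactly at every audit point,
        and the steady-state delivery current matches the capture rate."""
        res = sphere_sim_R10
        assert all(nc + ns == 1000 for _, nc, ns in res.audit)
        capture_rate = res.wall_stats.captures / res.config.T_total
        assert res.delivered_current == pytest.approx(capture_rate, rel=0.10)
        assert res.convergence_l1 < 0.05

    def test_deterministic_under_seed(self):
        cfg = SimConfig(N=200, T_total=5.0, burn_in=1.0, seed=7)
        a = run(cfg, G10)
        b = run(cfg, G10)
        assert np.array_equal(a.profile.counts, b.profile.counts)
        assert a.c0 == b.c0 and a.delivered_current == b.delivered_current
        c = run(SimConfig(N=200, T_total=5.0, burn_in=1.0, seed=8), G10)
        assert not np.array_equal(a.profile.counts, c.profile.counts)

    def test_reflecting_profile_is_flat(self, reflecting_sim):
        p = profiles.normalize(reflecting_sim.profile)
        sel = np.abs(p.z_centers) < 9.0  # pole-cap bins are noise-dominated
        assert np.max(np.abs(p.values[sel] - 1.0)) < 0.1

    def test_profile_shape_independent_of_transport_speed(self, sphere_sim_R10):
        """Raising v only repartitions particles between surface and
        cytoplasm; the normalized cytoplasmic profile is unchanged."""
        res5 = run(
            SimConfig(T_total=300.0, burn_in=80.0, seed=13, v=5.0), G10
        )
        p1 = profiles.normalize(sphere_sim_R10.profile)
        p5 = profiles.normalize(res5.profile)
        assert res5.surface_fraction < sphere_sim_R10.surface_fraction
        sel = (np.abs(p1.z_centers) < 9.0) & (p1.distance_from_pole > 1.0)
        assert np.max(np.abs(p1.values[sel] - p5.values[sel])) < 0.15

    def test_reactive_profile_matches_robin_oracle(self):
        """Simulated kon = 0.1 profile agrees with the independent
        Robin grid solution within sampling error."""
        res = run(SimConfig(T_total=400.0, burn_in=100.0, seed=12, kon=0.1), G10)
        sol = oracle.solve(G10, "robin", kon=0.1, D=1.0, n_s=120, n_t=240)
        p_sim = profiles.normalize(res.profile)
        p_orc = profiles.normalize(oracle.axial_profile(sol))
        sel = np.abs(p_sim.z_centers) < 9.5
        # deviation relative to the local level (+0.2 floor so sparse
        # posterior bins are judged on counting noise, not percentages)
        dev = np.abs(p_sim.values[sel] - p_orc.values[sel]) / (p_orc.values[sel] + 0.2)
        assert np.max(dev) < 0.12

    def test_near_surface_density_vanishes_with_perfect_absorption(self, sphere_sim_R10):
        """The absorbing condition drives the cytoplasmic density at
        the wall far below the cell average (posterior side checked,
        away from the source)."""
        p = profiles.normalize(sphere_sim_R10.profile)
        assert p.values[0] < 0.1  # most posterior bin hugs the surface
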