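"""Particle-based simulation of the polar transport model.

N protein molecules diffuse in the cytoplasm of an axisymmetric cell.
When a diffusing molecule hits the cell surface it is captured by the
cortical transport machinery — with probability one (perfect
absorption) or with a per-encounter probability derived from a surface
reactivity ``kon`` (partially absorbing wall) — and is then carried
deterministically along the surface toward the anterior pole at speed
``v``. After a transit time d/v, where d is the path length from the
capture point to the pole, the molecule is released back into the
cytoplasm at the release point r0 just inside the pole. Optionally a
bound molecule can detach mid-transit at rate γ = 1/t_bound and rejoin
the cytoplasm where it currently is. The total number of molecules is
conserved exactly.

Position updates are Euler–Maruyama: each Cartesian coordinate receives
an independent Gaussian increment of zero mean and variance 2·D·Δt.
Wall crossings are detected at the end of the step and resolved at the
segment/surface intersection; non-captured molecules are specularly
reflected about the tangent plane at the crossing point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .geometry import CellGeometry
from .profiles import ConcentrationProfile

__all__ = [
    "SimConfig",
    "ParticleSystem",
    "SimResult",
    "capture_probability",
    "diffusion_step",
    "handle_wall",
    "surface_step",
    "init_particles",
    "run",
    "PERFECT_ABSORPTION",
    "NO_DETACHMENT",
]

#: sentinel for kon meaning a perfectly absorbing surface (kon → ∞)
PERFECT_ABSORPTION = math.inf
#: sentinel for t_bound meaning molecules never detach during transit
NO_DETACHMENT = math.inf


@dataclass(frozen=True)
class SimConfig:
    """Physical and numerical parameters of one simulation run.

    Defaults are the standard conditions used throughout: D = 1 µm²/s,
    v = 1 µm/s, Δt = 0.001 s, N = 1000 molecules, perfectly absorbing
    surface and no detachment.
    """

    D: float = 1.0              # cytoplasmic diffusivity, µm²/s
    v: float = 1.0              # cortical transport speed, µm/s
    dt: float = 1e-3            # time step, s
    N: int = 1000               # number of molecules
    kon: float = PERFECT_ABSORPTION   # surface reactivity, µm/s
    t_bound: float = NO_DETACHMENT    # mean bound time 1/γ, s
    T_total: float = 600.0      # total simulated time, s
    burn_in: float | None = None  # discarded initial time, s (None → auto)
    n_bins: int = 50            # axial bins for the recorded profile
    seed: int = 0
    snapshot_interval: float = 0.5   # s between profile accumulations
    reentry_depth: float | None = None  # µm; None → sqrt(2 D dt)
    store_snapshots: int = 0    # number of full particle snapshots to keep

    def __post_init__(self) -> None:
        if self.D <= 0 or self.v <= 0 or self.dt <= 0:
            raise ValueError("D, v and dt must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.kon < 0:
            raise ValueError("kon must be nonnegative")
        if self.t_bound < 0:
            raise ValueError("t_bound must be nonnegative")
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.burn_in is not None and not self.T_total > self.burn_in >= 0:
            raise ValueError("need T_total > burn_in >= 0")

    def resolved_burn_in(self, g: CellGeometry) -> float:
        """Burn-in time; default 10·(polar extent)²/D, capped below T_total."""
        if self.burn_in is not None:
            return self.burn_in
        auto = 10.0 * g.polar_extent**2 / self.D
        if auto >= self.T_total:
            raise ValueError(
                "T_total too short for the automatic burn-in; set burn_in explicitly"
            )
        return auto

    def resolved_reentry_depth(self) -> float:
        if self.reentry_depth is not None:
            return self.reentry_depth
        return math.sqrt(2.0 * self.D * self.dt)


@dataclass
class ParticleSystem:
    """Evolving particle state. Cytoplasm + surface counts equal N always."""

    positions: np.ndarray       # (N, 3); meaningful only for cytoplasmic ones
    on_surface: np.ndarray      # (N,) bool
    transit_remaining: np.ndarray  # (N,) s; meaningful for surface particles
    transit_total: np.ndarray   # (N,) s; full transit time at capture
    azimuth: np.ndarray         # (N,) rad; meridian plane of the transport
    patch: np.ndarray           # (N,) int8; capture surface patch (cylinder)

    @property
    def n_cytoplasm(self) -> int:
        return int(np.count_nonzero(~self.on_surface))

    @property
    def n_surface(self) -> int:
        return int(np.count_nonzero(self.on_surface))


def init_particles(cfg: SimConfig, g: CellGeometry, rng: np.random.Generator) -> ParticleSystem:
    """All N molecules start in the cytoplasm, uniformly distributed."""
    pos = geo.sample_uniform_interior(g, cfg.N, rng)
    n = cfg.N
    return ParticleSystem(
        positions=pos,
        on_surface=np.zeros(n, dtype=bool),
        transit_remaining=np.zeros(n),
        transit_total=np.zeros(n),
        azimuth=np.zeros(n),
        patch=np.zeros(n, dtype=np.int8),
    )


def capture_probability(cfg: SimConfig) -> float:
    """Per-wall-encounter capture probability.

    1 for the perfectly absorbing surface. For a partially absorbing
    (reactive) surface with reactivity kon the standard Brownian
    dynamics discretization is P = kon·sqrt(π·Δt/D), clamped to [0, 1];
    it reproduces the continuum Robin condition −D ∂c/∂n = kon·c as
    Δt → 0 and is validated here against the grid solver.
    """
    if cfg.kon < 0:
        raise ValueError("kon must be nonnegative")
    if math.isinf(cfg.kon):
        return 1.0
    return min(1.0, cfg.kon * math.sqrt(math.pi * cfg.dt / cfg.D))


def diffusion_step(positions: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Proposed positions after one free Gaussian step (no walls)."""
    sigma = math.sqrt(2.0 * cfg.D * cfg.dt)
    return positions + sigma * rng.standard_normal(positions.shape)


@dataclass
class WallStats:
    encounters: int = 0
    captures: int = 0
    redraws: int = 0
    stuck: int = 0   # particles left at their previous position


def handle_wall(
    g: CellGeometry,
    cfg: SimConfig,
    p_old: np.ndarray,
    p_prop: np.ndarray,
    rng: np.random.Generator,
    stats: WallStats | None = None,
    max_redraw: int = 10,
):
    """Resolve wall interactions for one batch of proposed moves.

    Parameters are the pre-step positions ``p_old`` (all inside) and
    the proposed positions ``p_prop`` of the same particles. Returns
    ``(new_positions, captured_mask, capture_points)`` where captured
    particles have left the cytoplasm at the returned surface points
    and the remaining particles' new positions are inside the cell.
    """
    if stats is None:
        stats = WallStats()
    m = len(p_old)
    new_pos = p_prop.copy()
    captured = np.zeros(m, dtype=bool)
    cap_points = np.zeros((m, 3))
    P = capture_probability(cfg)

    pending = np.nonzero(~geo.contains(g, p_prop))[0]
    stats.encounters += len(pending)
    end = p_prop[pending].copy()
    for _ in range(max_redraw):
        if len(pending) == 0:
            break
        s = geo.boundary_crossing(g, p_old[pending], end)
        cap = rng.random(len(pending)) < P
        idx_cap = pending[cap]
        captured[idx_cap] = True
        cap_points[idx_cap] = s[cap]
        stats.captures += len(idx_cap)
        # specular reflection of the rest about the tangent plane at s
        pending = pending[~cap]
        if len(pending) == 0:
            break
        s_r = s[~cap]
        end = end[~cap]
        n_out = -geo.inward_normal(g, s_r)
        overshoot = np.sum((end - s_r) * n_out, axis=1)
        end = end - 2.0 * overshoot[:, None] * n_out
        ok = geo.contains(g, end)
        new_pos[pending[ok]] = end[ok]
        # reflected point still outside (strongly curved surface or a
        # cylinder corner): re-draw that particle's whole step
        pending = pending[~ok]
        if len(pending) == 0:
            break
        stats.redraws += len(pending)
        end = diffusion_step(p_old[pending], cfg, rng)
        ok = geo.contains(g, end)
        new_pos[pending[ok]] = end[ok]
        inside_now = pending[ok]
        pending = pending[~ok]
        end = end[np.nonzero(~ok)[0]] if len(pending) else end[:0]
        stats.encounters += len(pending)
        del inside_now
    if len(pending):
        # give up after max_redraw attempts: keep the old position
        stats.stuck += len(pending)
        new_pos[pending] = p_old[pending]

    # Brownian-bridge interior capture (perfect absorption only): a
    # step whose endpoints both lie inside may still have touched the
    # wall in between, with probability exp(−h1·h2/(D·Δt)) for start
    # and end wall distances h1, h2. Ignoring these touches makes the
    # wall act slightly displaced outward (an O(√Δt) bias); for the
    # reactive wall the per-encounter probability used above is the
    # standard calibration of the plain end-of-step scheme, so no
    # extra correction is applied there.
    if math.isinf(cfg.kon):
        stay = np.nonzero(~captured)[0]
        h1 = geo.surface_distance(g, p_old[stay])
        h2 = geo.surface_distance(g, new_pos[stay])
        hh = np.maximum(h1, 0) * np.maximum(h2, 0)
        Ddt = cfg.D * cfg.dt
        near = stay[hh < 18.0 * Ddt]
        if len(near):
            p_touch = np.exp(-hh[hh < 18.0 * Ddt] / Ddt)
            hit = near[rng.random(len(near)) < p_touch]
            if len(hit):
                captured[hit] = True
                cap_points[hit] = geo.project_to_surface(g, new_pos[hit])
                stats.encounters += len(hit)
                stats.captures += len(hit)
    return new_pos, captured, cap_points


def surface_step(
    ps: ParticleSystem,
    cfg: SimConfig,
    g: CellGeometry,
    rng: np.random.Generator,
) -> int:
    """Advance surface-bound particles by one time step.

    Each bound particle may first detach (probability Δt/t_bound) and
    rejoin the cytoplasm at its current transport position, displaced
    inward by the re-entry depth. Remaining particles have their
    transit countdown decremented; those reaching zero are released at
    r0. Returns the number of releases.
    """
    surf_idx = np.nonzero(ps.on_surface)[0]
    if len(surf_idx) == 0:
        return 0
    if math.isfinite(cfg.t_bound):
        p_det = min(1.0, cfg.dt / cfg.t_bound) if cfg.t_bound > 0 else 1.0
        det = rng.random(len(surf_idx)) < p_det
        det_idx = surf_idx[det]
        if len(det_idx):
            d_rem = cfg.v * ps.transit_remaining[det_idx]
            pts = geo.meridian_point_at_arc(
                g, d_rem, ps.azimuth[det_idx], ps.patch[det_idx]
            )
            n_in = geo.inward_normal(g, pts)
            depth = cfg.resolved_reentry_depth()
            cand = pts + depth * n_in
            bad = ~geo.contains(g, cand)
            if np.any(bad):
                # pull toward the cell centre instead (convexity keeps
                # the scaled point strictly inside)
                norms = np.linalg.norm(pts[bad], axis=1)
                norms = np.where(norms > 0, norms, 1.0)
                cand[bad] = pts[bad] * (1.0 - depth / norms)[:, None]
            ps.positions[det_idx] = cand
            ps.on_surface[det_idx] = False
        surf_idx = surf_idx[~det]
    if len(surf_idx) == 0:
        return 0
    ps.transit_remaining[surf_idx] -= cfg.dt
    done = surf_idx[ps.transit_remaining[surf_idx] <= 0.0]
    if len(done):
        ps.positions[done] = geo.release_point(g)
        ps.on_surface[done] = False
    return len(done)


def _capture(ps: ParticleSystem, cfg: SimConfig, g: CellGeometry,
             idx: np.ndarray, points: np.ndarray) -> None:
    d = np.atleast_1d(geo.arc_to_anterior_pole(g, points))
    ps.on_surface[idx] = True
    ps.transit_remaining[idx] = d / cfg.v
    ps.transit_total[idx] = d / cfg.v
    ps.azimuth[idx] = np.arctan2(points[:, 1], points[:, 0])
    ps.patch[idx] = geo.classify_surface(g, points)


def step(
    ps: ParticleSystem,
    cfg: SimConfig,
    g: CellGeometry,
    rng: np.random.Generator,
    stats: WallStats | None = None,
) -> int:
    """One full update: diffuse cytoplasmic particles, resolve wall
    interactions, advance surface transport. Returns releases count."""
    cyt_idx = np.nonzero(~ps.on_surface)[0]
    if len(cyt_idx):
        old = ps.positions[cyt_idx]
        prop = diffusion_step(old, cfg, rng)
        new_pos, captured, cap_pts = handle_wall(g, cfg, old, prop, rng, stats)
        keep = ~captured
        ps.positions[cyt_idx[keep]] = new_pos[keep]
        if np.any(captured):
            _capture(ps, cfg, g, cyt_idx[captured], cap_pts[captured])
    return surface_step(ps, cfg, g, rng)


@dataclass
class SimResult:
    profile: ConcentrationProfile
    c0: float                    # mean cytoplasmic concentration, µm⁻³
    delivered_current: float     # releases per second in steady state
    surface_fraction: float      # time-averaged fraction bound to the surface
    convergence_l1: float        # L1 distance between half-window profiles
    wall_stats: WallStats
    audit: list                  # (step, n_cytoplasm, n_surface) every 10⁴ steps
    snapshots: list              # optional (t, positions, on_surface) tuples
    config: SimConfig = None
    geometry: CellGeometry = None


def run(cfg: SimConfig, g: CellGeometry) -> SimResult:
    """Run the simulation and accumulate the steady-state axial profile.

    The profile is the time average, over [burn_in, T_total] sampled
    every ``snapshot_interval``, of the histogram of cytoplasmic
    particle z positions, converted to a concentration by dividing by
    the slice volume and the number of samples. Convergence is
    diagnosed by the L1 distance between the normalized profiles of the
    two halves of the recording window.
    """
    burn_in = cfg.resolved_burn_in(g)
    if cfg.T_total <= burn_in:
        raise ValueError("T_total must exceed burn_in")
    rng = np.random.default_rng(cfg.seed)
    ps = init_particles(cfg, g, rng)
    stats = WallStats()

    ext = g.polar_extent
    edges = np.linspace(-ext, ext, cfg.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # slice volumes: V_i = ∫ π ρ(z)² dz over the bin (exact per shape)
    bin_volumes = _slice_volumes(g, edges)

    n_steps = int(round(cfg.T_total / cfg.dt))
    burn_steps = int(round(burn_in / cfg.dt))
    snap_every = max(1, int(round(cfg.snapshot_interval / cfg.dt)))

    counts = np.zeros(cfg.n_bins)
    counts_half = [np.zeros(cfg.n_bins), np.zeros(cfg.n_bins)]
    n_samples = 0
    cyt_total = 0.0
    surf_total = 0.0
    releases = 0
    audit = []
    snapshots = []
    snap_store_every = (
        max(1, (n_steps - burn_steps) // max(cfg.store_snapshots, 1))
        if cfg.store_snapshots
        else 0
    )
    half_step = burn_steps + (n_steps - burn_steps) // 2

    for k in range(1, n_steps + 1):
        nrel = step(ps, cfg, g, rng, stats)
        if k > burn_steps:
            releases += nrel
            if k % snap_every == 0:
                z = ps.positions[~ps.on_surface, 2]
                h, _ = np.histogram(z, bins=edges)
                counts += h
                counts_half[0 if k <= half_step else 1] += h
                n_samples += 1
                cyt_total += len(z)
                surf_total += ps.on_surface.sum()
            if cfg.store_snapshots and k % snap_store_every == 0:
                snapshots.append(
                    (k * cfg.dt, ps.positions.copy(), ps.on_surface.copy())
                )
        if k % 10_000 == 0:
            nc, nsurf = ps.n_cytoplasm, ps.n_surface
            audit.append((k, nc, nsurf))
            assert nc + nsurf == cfg.N, "particle conservation violated"

    if n_samples == 0:
        raise ValueError("recording window contains no snapshots")
    values = counts / (n_samples * bin_volumes)
    c0 = cyt_total / n_samples / geo.volume(g)
    conv = _half_window_l1(counts_half, bin_volumes)
    profile = ConcentrationProfile(
        z_centers=centers,
        values=values,
        c0=c0,
        z_anterior=ext,
        bin_volumes=bin_volumes,
        counts=counts,
        metadata={
            "source": "simulation",
            "shape": g.shape,
            "R": g.R,
            "a": g.a,
            "L": g.L,
            "epsilon": g.epsilon,
            "D": cfg.D,
            "v": cfg.v,
            "dt": cfg.dt,
            "N": cfg.N,
            "kon": None if math.isinf(cfg.kon) else cfg.kon,
            "t_bound": None if math.isinf(cfg.t_bound) else cfg.t_bound,
            "T_total": cfg.T_total,
            "burn_in": burn_in,
            "seed": cfg.seed,
            "n_samples": n_samples,
        },
    )
    rec_time = (n_steps - burn_steps) * cfg.dt
    return SimResult(
        profile=profile,
        c0=c0,
        delivered_current=releases / rec_time,
        surface_fraction=surf_total / (cyt_total + surf_total),
        convergence_l1=conv,
        wall_stats=stats,
        audit=audit,
        snapshots=snapshots,
        config=cfg,
        geometry=g,
    )


def _slice_volumes(g: CellGeometry, edges: np.ndarray) -> np.ndarray:
    """Exact volume of each axial slice, ∫ π ρ(z)² dz over the bin."""
    def cum(z):
        if g.shape == "sphere":
            return np.pi * (g.R**2 * z - z**3 / 3.0)
        if g.shape == "cylinder":
            return np.pi * g.R**2 * z
        return np.pi * g.R**2 * (z - z**3 / (3.0 * g.a**2))
    return cum(edges[1:]) - cum(edges[:-1])


def _half_window_l1(counts_half, bin_volumes) -> float:
    """L1 distance between the normalized profiles of the two halves."""
    out = []
    for c in counts_half:
        tot = c.sum()
        if tot == 0:
            return math.inf
        dens = c / bin_volumes
        out.append(dens / (np.sum(dens * bin_volumes) / np.sum(bin_volumes)))
    w = bin_volumes / bin_volumes.sum()
    return float(np.sum(np.abs(out[0] - out[1]) * w))
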