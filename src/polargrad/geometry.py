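"""Axisymmetric cell geometries: sphere, cylinder, spheroid.

The polar (symmetry) axis is z, with the anterior pole at z > 0. All
lengths are in micrometres. Three closed convex shapes are supported:

* ``sphere`` of radius ``R`` — poles at (0, 0, ±R);
* ``cylinder`` of radius ``R`` and half-length ``L`` (total length 2L) —
  poles at (0, 0, ±L), the surface consisting of the lateral wall and
  the two flat end caps;
* ``spheroid`` with equatorial radius ``R`` and polar semi-axis
  ``a >= R`` — implicit surface (x² + y²)/R² + z²/a² = 1, poles at
  (0, 0, ±a).

Proteins delivered by the cortical transport are released at the
*release point* ``r0``, a small distance ``epsilon`` inside the anterior
pole along the axis. By default ``epsilon`` is 5% of the polar
semi-extent so that it scales with cell size, which is what makes the
normalized gradient a function of relative position only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipeinc
from scipy.optimize import brentq

__all__ = [
    "CellGeometry",
    "contains",
    "cross_section_radius",
    "boundary_crossing",
    "inward_normal",
    "arc_to_anterior_pole",
    "meridian_point_at_arc",
    "release_point",
    "volume",
    "sample_uniform_interior",
    "SURFACE_LATERAL",
    "SURFACE_ANTERIOR_CAP",
    "SURFACE_POSTERIOR_CAP",
]

# Surface-patch identifiers (cylinder only has more than one patch).
SURFACE_LATERAL = 0
SURFACE_ANTERIOR_CAP = 1
SURFACE_POSTERIOR_CAP = 2

#: default release offset as a fraction of the polar semi-extent
DEFAULT_EPSILON_FRACTION = 0.05

#: relative tolerance (of the relevant semi-axis) for "point on surface"
SURFACE_RTOL = 1e-6


@dataclass(frozen=True)
class CellGeometry:
    """Parametric axisymmetric cell shape.

    Parameters
    ----------
    shape : {"sphere", "cylinder", "spheroid"}
    R : float
        Sphere radius; cylinder radius; spheroid equatorial (minor)
        semi-axis. µm.
    a : float, optional
        Spheroid polar semi-axis (must satisfy ``a >= R``). Ignored for
        sphere and cylinder.
    L : float, optional
        Cylinder *half*-length (the cylinder spans ``-L <= z <= L``).
        Ignored otherwise.
    epsilon : float, optional
        Release offset from the anterior pole along the axis. Defaults
        to 5% of the polar semi-extent.
    """

    shape: str
    R: float
    a: float = 0.0
    L: float = 0.0
    epsilon: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "spheroid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.shape == "spheroid" and self.a < self.R:
            raise ValueError("spheroid requires a >= R")
        if self.shape == "cylinder" and self.L <= 0:
            raise ValueError("cylinder requires L > 0")
        if self.epsilon < 0:
            object.__setattr__(
                self, "epsilon", DEFAULT_EPSILON_FRACTION * self.polar_extent
            )
        if not 0 < self.epsilon < self.polar_extent:
            raise ValueError("epsilon must lie in (0, polar extent)")

    # -- constructors -------------------------------------------------
    @classmethod
    def sphere(cls, R: float, epsilon: float | None = None) -> "CellGeometry":
        return cls("sphere", R, epsilon=-1.0 if epsilon is None else epsilon)

    @classmethod
    def cylinder(cls, R: float, L: float, epsilon: float | None = None) -> "CellGeometry":
        return cls("cylinder", R, L=L, epsilon=-1.0 if epsilon is None else epsilon)

    @classmethod
    def spheroid(cls, R: float, a: float, epsilon: float | None = None) -> "CellGeometry":
        return cls("spheroid", R, a=a, epsilon=-1.0 if epsilon is None else epsilon)

    # -- basic queries ------------------------------------------------
    @property
    def polar_extent(self) -> float:
        """Distance from the centre to a pole along the z axis (µm)."""
        if self.shape == "sphere":
            return self.R
        if self.shape == "cylinder":
            return self.L
        return self.a

    @property
    def anterior_pole(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.polar_extent])

    @property
    def posterior_pole(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.polar_extent])

    @property
    def surface_tolerance(self) -> float:
        """Absolute length below which a point counts as on the surface."""
        return SURFACE_RTOL * max(self.R, self.polar_extent)


def _as_points(p) -> tuple[np.ndarray, bool]:
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    return np.atleast_2d(p), single


def contains(g: CellGeometry, p) -> np.ndarray | bool:
    """True where ``p`` lies strictly inside the cell body.

    ``p`` may be a single 3-vector or an (n, 3) array.
    """
    pts, single = _as_points(p)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if g.shape == "sphere":
        inside = x * x + y * y + z * z < g.R * g.R
    elif g.shape == "cylinder":
        inside = (x * x + y * y < g.R * g.R) & (np.abs(z) < g.L)
    else:
        inside = (x * x + y * y) / g.R**2 + z * z / g.a**2 < 1.0
    return bool(inside[0]) if single else inside


def cross_section_radius(g: CellGeometry, z) -> np.ndarray | float:
    """Radius ρ(z) of the circular cross section at height z (µm)."""
    z_arr = np.asarray(z, dtype=float)
    ext = g.polar_extent
    if np.any(np.abs(z_arr) > ext * (1 + 1e-12)):
        raise ValueError("z outside the cell")
    z_arr = np.clip(z_arr, -ext, ext)
    if g.shape == "sphere":
        out = np.sqrt(np.maximum(g.R**2 - z_arr**2, 0.0))
    elif g.shape == "cylinder":
        out = np.full_like(z_arr, g.R)
    else:
        out = g.R * np.sqrt(np.maximum(1.0 - (z_arr / g.a) ** 2, 0.0))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def _implicit(g: CellGeometry, pts: np.ndarray) -> np.ndarray:
    """Signed implicit surface function, < 0 inside, = 0 on surface."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if g.shape == "sphere":
        return (x * x + y * y + z * z) / g.R**2 - 1.0
    if g.shape == "spheroid":
        return (x * x + y * y) / g.R**2 + z * z / g.a**2 - 1.0
    # cylinder: max of lateral and cap constraints
    return np.maximum((x * x + y * y) / g.R**2 - 1.0, np.abs(z) / g.L - 1.0)


def on_surface(g: CellGeometry, p) -> np.ndarray | bool:
    pts, single = _as_points(p)
    tol = 4.0 * SURFACE_RTOL  # tolerance on the dimensionless implicit value
    res = np.abs(_implicit(g, pts)) < tol
    return bool(res[0]) if single else res


def boundary_crossing(g: CellGeometry, p_in, p_out) -> np.ndarray:
    """Intersection of the segment [p_in, p_out] with the cell surface.

    ``p_in`` must be inside and ``p_out`` outside; both may be (n, 3)
    arrays. The crossing is found in closed form (the implicit surface
    function is quadratic, or piecewise planar/quadratic for the
    cylinder, along the segment).
    """
    a_pts, single = _as_points(p_in)
    b_pts, _ = _as_points(p_out)
    if a_pts.shape != b_pts.shape:
        raise ValueError("p_in and p_out must have matching shapes")
    if not np.all(contains(g, a_pts)):
        raise ValueError("p_in must be inside the cell")
    if np.any(contains(g, b_pts)):
        raise ValueError("p_out must be outside the cell")

    d = b_pts - a_pts
    if g.shape in ("sphere", "spheroid"):
        az = g.a if g.shape == "spheroid" else g.R
        scale = np.array([g.R, g.R, az])
        u = a_pts / scale
        w = d / scale
        A = np.sum(w * w, axis=1)
        B = 2.0 * np.sum(u * w, axis=1)
        C = np.sum(u * u, axis=1) - 1.0
        disc = np.maximum(B * B - 4 * A * C, 0.0)
        t = (-B + np.sqrt(disc)) / (2 * A)
    else:
        t = np.full(len(a_pts), np.inf)
        # lateral wall: quadratic in (x, y)
        A = d[:, 0] ** 2 + d[:, 1] ** 2
        B = 2 * (a_pts[:, 0] * d[:, 0] + a_pts[:, 1] * d[:, 1])
        C = a_pts[:, 0] ** 2 + a_pts[:, 1] ** 2 - g.R**2
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = B * B - 4 * A * C
            valid = (A > 0) & (disc >= 0)
            t_lat = np.where(valid, (-B + np.sqrt(np.maximum(disc, 0))) / (2 * A), np.inf)
        t_lat = np.where((t_lat >= 0) & (t_lat <= 1), t_lat, np.inf)
        t = np.minimum(t, t_lat)
        # end caps: planes z = ±L
        for zc in (g.L, -g.L):
            with np.errstate(divide="ignore", invalid="ignore"):
                t_cap = (zc - a_pts[:, 2]) / d[:, 2]
            t_cap = np.where(np.isfinite(t_cap) & (t_cap >= 0) & (t_cap <= 1), t_cap, np.inf)
            t = np.minimum(t, t_cap)
    if np.any(~np.isfinite(t)) or np.any(t > 1 + 1e-12):
        raise ValueError("no surface crossing found on the segment")
    s = a_pts + t[:, None] * d
    return s[0] if single else s


def classify_surface(g: CellGeometry, s) -> np.ndarray | int:
    """Which surface patch a surface point belongs to (cylinder caps)."""
    pts, single = _as_points(s)
    if g.shape != "cylinder":
        out = np.full(len(pts), SURFACE_LATERAL, dtype=np.int8)
    else:
        tol = g.surface_tolerance
        out = np.full(len(pts), SURFACE_LATERAL, dtype=np.int8)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        on_lat = np.abs(rho - g.R) <= tol
        out[~on_lat & (pts[:, 2] > 0)] = SURFACE_ANTERIOR_CAP
        out[~on_lat & (pts[:, 2] < 0)] = SURFACE_POSTERIOR_CAP
    return int(out[0]) if single else out


def inward_normal(g: CellGeometry, s) -> np.ndarray:
    """Unit normal at surface point(s) ``s`` pointing into the cell."""
    pts, single = _as_points(s)
    if not np.all(on_surface(g, pts)):
        raise ValueError("point not on the cell surface")
    if g.shape == "sphere":
        n = -pts / np.linalg.norm(pts, axis=1, keepdims=True)
    elif g.shape == "spheroid":
        grad = np.column_stack(
            [2 * pts[:, 0] / g.R**2, 2 * pts[:, 1] / g.R**2, 2 * pts[:, 2] / g.a**2]
        )
        n = -grad / np.linalg.norm(grad, axis=1, keepdims=True)
    else:
        patch = classify_surface(g, pts)
        n = np.zeros_like(pts)
        lat = patch == SURFACE_LATERAL
        rho = np.hypot(pts[lat, 0], pts[lat, 1])
        rho = np.where(rho > 0, rho, 1.0)
        n[lat, 0] = -pts[lat, 0] / rho
        n[lat, 1] = -pts[lat, 1] / rho
        n[patch == SURFACE_ANTERIOR_CAP, 2] = -1.0
        n[patch == SURFACE_POSTERIOR_CAP, 2] = 1.0
    return n[0] if single else n


def arc_to_anterior_pole(g: CellGeometry, s) -> np.ndarray | float:
    """Transport path length d from a capture point to the anterior pole.

    Sphere: the great-circle arc R·arccos(z/R). Cylinder lateral wall:
    L − z (the straight meridian run to the anterior
    rim); anterior cap: the in-cap radial run ρ to the axis; posterior
    cap: (R − ρ) + 2L (across the cap to the rim, then the full lateral
    run). Spheroid: the meridian elliptic arc
    a·[E(π/2, k) − E(φ, k)] with φ = arcsin(z/a), k² = 1 − R²/a².
    """
    pts, single = _as_points(s)
    if not np.all(on_surface(g, pts)):
        raise ValueError("point not on the cell surface")
    z = pts[:, 2]
    if g.shape == "sphere":
        d = g.R * np.arccos(np.clip(z / g.R, -1.0, 1.0))
    elif g.shape == "spheroid":
        m = 1.0 - g.R**2 / g.a**2
        phi = np.arcsin(np.clip(z / g.a, -1.0, 1.0))
        d = g.a * (ellipe(m) - ellipeinc(phi, m))
    else:
        patch = classify_surface(g, pts)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        d = g.L - z  # lateral default
        d = np.where(patch == SURFACE_ANTERIOR_CAP, rho, d)
        d = np.where(patch == SURFACE_POSTERIOR_CAP, (g.R - rho) + 2 * g.L, d)
    return float(d[0]) if single else d


def meridian_point_at_arc(
    g: CellGeometry, d, azimuth, surface_patch=None
) -> np.ndarray:
    """Surface point at transport path length ``d`` from the anterior pole.

    Inverse of :func:`arc_to_anterior_pole` along the transport path;
    used to locate a particle that detaches mid-transit. ``azimuth`` is
    the meridian plane angle. For cylinders the original capture patch
    decides which branch of the path the particle is on.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    az = np.atleast_1d(np.asarray(azimuth, dtype=float))
    if g.shape == "sphere":
        theta = np.clip(d / g.R, 0.0, np.pi)
        rho = g.R * np.sin(theta)
        z = g.R * np.cos(theta)
    elif g.shape == "spheroid":
        m = 1.0 - g.R**2 / g.a**2
        total = g.a * ellipe(m)
        phi = np.empty_like(d)
        for i, di in enumerate(d):
            target = np.clip(di, 0.0, 2 * total)
            # d(φ) = a [E(π/2) − E(φ)] is monotone decreasing in φ
            fun = lambda p: g.a * (ellipe(m) - ellipeinc(p, m)) - target
            phi[i] = brentq(fun, -np.pi / 2, np.pi / 2) if fun(-np.pi / 2) > 0 else -np.pi / 2
        rho = g.R * np.cos(phi)
        z = g.a * np.sin(phi)
    else:
        if surface_patch is None:
            surface_patch = np.full(len(d), SURFACE_LATERAL, dtype=np.int8)
        surface_patch = np.atleast_1d(surface_patch)
        rho = np.empty_like(d)
        z = np.empty_like(d)
        lat = surface_patch == SURFACE_LATERAL
        rho[lat] = g.R
        z[lat] = g.L - d[lat]
        ant = surface_patch == SURFACE_ANTERIOR_CAP
        rho[ant] = np.minimum(d[ant], g.R)
        z[ant] = g.L
        post = surface_patch == SURFACE_POSTERIOR_CAP
        # remaining path > 2L means the particle is still on the cap
        on_cap = post & (d > 2 * g.L)
        rho[post] = g.R
        z[post] = np.clip(g.L - d[post], -g.L, g.L)
        rho[on_cap] = np.clip(g.R - (d[on_cap] - 2 * g.L), 0.0, g.R)
        z[on_cap] = -g.L
    pts = np.column_stack([rho * np.cos(az), rho * np.sin(az), z])
    return pts


def surface_distance(g: CellGeometry, p) -> np.ndarray | float:
    """Distance from interior point(s) to the cell surface.

    Exact for sphere and cylinder. For the spheroid it is the
    first-order level-set estimate (1 − √F)·√F/|∇(√F)| with
    F = (x²+y²)/R² + z²/a², accurate near the surface where it is
    used (wall-interaction bookkeeping).
    """
    pts, single = _as_points(p)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if g.shape == "sphere":
        d = g.R - np.sqrt(x * x + y * y + z * z)
    elif g.shape == "cylinder":
        d = np.minimum(g.R - np.hypot(x, y), g.L - np.abs(z))
    else:
        F = (x * x + y * y) / g.R**2 + z * z / g.a**2
        sF = np.sqrt(np.maximum(F, 1e-300))
        gn = np.sqrt((x * x + y * y) / g.R**4 + z * z / g.a**4)
        gn = np.where(gn > 0, gn, 1.0)
        d = (1.0 - sF) * sF / gn
    return float(d[0]) if single else d


def project_to_surface(g: CellGeometry, p) -> np.ndarray:
    """Nearest-surface projection of near-surface interior point(s)."""
    pts, single = _as_points(p)
    out = pts.copy()
    if g.shape == "sphere":
        r = np.linalg.norm(pts, axis=1, keepdims=True)
        out = pts * (g.R / np.where(r > 0, r, 1.0))
    elif g.shape == "cylinder":
        rho = np.hypot(pts[:, 0], pts[:, 1])
        to_lat = g.R - rho
        to_cap = g.L - np.abs(pts[:, 2])
        lat = to_lat <= to_cap
        f = g.R / np.where(rho > 0, rho, 1.0)
        out[lat, 0] *= f[lat]
        out[lat, 1] *= f[lat]
        out[~lat, 2] = np.copysign(g.L, pts[~lat, 2])
    else:
        F = (pts[:, 0] ** 2 + pts[:, 1] ** 2) / g.R**2 + pts[:, 2] ** 2 / g.a**2
        t = 1.0 / np.sqrt(np.maximum(F, 1e-300))
        out = pts * t[:, None]
    return out[0] if single else out


def release_point(g: CellGeometry) -> np.ndarray:
    """Release point r0 = anterior pole − (0, 0, ε)."""
    return g.anterior_pole - np.array([0.0, 0.0, g.epsilon])


def volume(g: CellGeometry) -> float:
    """Cell volume in µm³."""
    if g.shape == "sphere":
        return 4.0 / 3.0 * np.pi * g.R**3
    if g.shape == "cylinder":
        return 2.0 * np.pi * g.R**2 * g.L
    return 4.0 / 3.0 * np.pi * g.R**2 * g.a


def sample_uniform_interior(g: CellGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. points uniform in the cell body, as an (n, 3) array.

    Uses exact transforms: uniform ball for the sphere, z-stretched
    ball for the spheroid, (√u, uniform z) for the cylinder.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, 3))
    if g.shape == "cylinder":
        rho = g.R * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        z = g.L * (2 * rng.random(n) - 1)
        return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    # uniform ball, then stretch z for the spheroid
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = g.R * rng.random(n) ** (1.0 / 3.0)
    pts = v * r[:, None]
    if g.shape == "spheroid":
        pts[:, 2] *= g.a / g.R
    return pts
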