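"""Numerical oracle: axisymmetric solver for the steady gradient.

Solves the steady problem ∇²c = −q δ(r − r0) inside any of the three
cell shapes with either a Dirichlet surface condition (c = 0, perfectly
absorbing cortex) or a Robin condition (−D ∂c/∂n = kon·c, partially
absorbing cortex), on the meridian half-plane (ρ, z).

Method
------
The point source is removed by singularity subtraction: write
c = G + u with G = q/(4π|r − r0|) the free-space Green's function.
Then u is harmonic and smooth, and carries inhomogeneous boundary data

* Dirichlet:  u = −G on the surface;
* Robin:      ∂u/∂n + (kon/D) u = −[(kon/D) G + ∂G/∂n] on the surface
  (n the outward normal),

which is discretized with axisymmetric linear (P1) finite elements on
a boundary-fitted structured mesh of the meridian domain — mesh rows
are discs of constant z, so disc-averaged profiles fall out of the
solution directly. The Robin boundary term is a natural (weak-form)
surface integral, so no one-sided normal stencils are needed and the
curved surface enters only through the mesh polygon. This solver is
independent of both the closed-form solutions and the particle
simulation, and serves as the oracle for the spheroid and for
imperfect-capture (Robin) cases that have no closed form here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry as geo
from .geometry import CellGeometry
from .profiles import ConcentrationProfile, binned_profile_from_function

__all__ = ["AxisymGrid", "GridSolution", "build_grid", "solve", "axial_profile"]


@dataclass(frozen=True)
class AxisymGrid:
    """Boundary-fitted structured mesh of the meridian half-plane.

    Nodes lie on rows of constant z (each row is a disc of the cell);
    row j has radial positions s_i·ρ(z_j). Rows where ρ(z_j) = 0 (the
    poles of sphere/spheroid) collapse to a single node.
    """

    nodes: np.ndarray            # (n, 2) columns (ρ, z)
    triangles: np.ndarray        # (m, 3) node ids, CCW
    rows: list                   # per row: array of node ids (axis → surface)
    z_rows: np.ndarray           # z of each row, descending (anterior first)
    surface_edges: np.ndarray    # (e, 2) node id pairs on the cell surface
    surface_normals: np.ndarray  # (e, 2) outward unit normals (ρ, z) per edge
    boundary_nodes: np.ndarray   # unique surface node ids
    logical: np.ndarray = None   # (n_t+1, n_s+1) node ids on the (t, s) grid


def build_grid(g: CellGeometry, n_s: int = 200, n_t: int = 400) -> AxisymGrid:
    """Mesh with n_s radial intervals and n_t meridional intervals.

    The z rows follow a cosine distribution, clustering resolution
    near the poles where the source sits and the profile varies fast.
    """
    ext = g.polar_extent
    z_rows = ext * np.cos(np.linspace(0.0, np.pi, n_t + 1))
    # keep rows strictly inside the polar extent for ρ(z) evaluation
    s = np.linspace(0.0, 1.0, n_s + 1)

    node_id = np.full((n_t + 1, n_s + 1), -1, dtype=int)
    coords: list[tuple[float, float]] = []
    for j, zj in enumerate(z_rows):
        rho_j = geo.cross_section_radius(g, float(np.clip(zj, -ext, ext)))
        if rho_j <= 0:
            nid = len(coords)
            coords.append((0.0, float(zj)))
            node_id[j, :] = nid
        else:
            for i, si in enumerate(s):
                node_id[j, i] = len(coords)
                coords.append((float(si * rho_j), float(zj)))
    nodes = np.asarray(coords)

    tris = []
    for j in range(n_t):
        for i in range(n_s):
            a = node_id[j, i]
            b = node_id[j, i + 1]
            c = node_id[j + 1, i + 1]
            d = node_id[j + 1, i]
            for tri in ((a, b, c), (a, c, d)):
                if len(set(tri)) == 3:
                    tris.append(tri)
    triangles = np.asarray(tris, dtype=int)
    # enforce positive (CCW) orientation
    p = nodes[triangles]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    triangles[flip] = triangles[flip][:, ::-1]
    keep = np.abs(area2) > 1e-14 * max(g.R, ext) ** 2
    triangles = triangles[keep]

    # surface edges: outer column, plus the end-cap rows of a cylinder
    edges = []
    outer = node_id[:, n_s]
    for j in range(n_t):
        if outer[j] != outer[j + 1]:
            edges.append((outer[j], outer[j + 1]))
    if g.shape == "cylinder":
        for row in (node_id[0], node_id[n_t]):
            for i in range(n_s):
                if row[i] != row[i + 1]:
                    edges.append((row[i], row[i + 1]))
    surface_edges = np.asarray(edges, dtype=int)

    # outward normal per edge: rotate the tangent, orient by testing a
    # point nudged off the midpoint
    p0 = nodes[surface_edges[:, 0]]
    p1 = nodes[surface_edges[:, 1]]
    t = p1 - p0
    ln = np.linalg.norm(t, axis=1, keepdims=True)
    nrm = np.column_stack([t[:, 1], -t[:, 0]]) / ln
    mid = 0.5 * (p0 + p1)
    delta = 1e-6 * max(g.R, ext)
    test = mid + delta * nrm
    test3 = np.column_stack([test[:, 0], np.zeros(len(test)), test[:, 1]])
    inward = geo.contains(g, test3)
    nrm[inward] *= -1.0

    rows = [node_id[j][np.concatenate(([True], np.diff(node_id[j]) != 0))]
            for j in range(n_t + 1)]
    boundary_nodes = np.unique(surface_edges)
    return AxisymGrid(
        nodes=nodes,
        triangles=triangles,
        rows=rows,
        z_rows=z_rows,
        surface_edges=surface_edges,
        surface_normals=nrm,
        boundary_nodes=boundary_nodes,
        logical=node_id,
    )


@dataclass
class GridSolution:
    grid: AxisymGrid
    geometry: CellGeometry
    c: np.ndarray              # nodal concentration (= G + u)
    u: np.ndarray              # smooth remainder
    q: float
    bc: str                    # "dirichlet" | "robin" | "uniform"
    kon: float | None
    D: float
    residual: float
    gauss_defect: float        # |surface flux − q| / q


def _greens(q: float, r0_z: float, rho: np.ndarray, z: np.ndarray) -> np.ndarray:
    d = np.sqrt(rho**2 + (z - r0_z) ** 2)
    d = np.maximum(d, 1e-300)
    return q / (4 * np.pi * d)


def _greens_grad(q: float, r0_z: float, rho, z):
    """(∂G/∂ρ, ∂G/∂z) of the free-space Green's function."""
    dz = z - r0_z
    d3 = (rho**2 + dz**2) ** 1.5
    d3 = np.maximum(d3, 1e-300)
    pref = -q / (4 * np.pi)
    return pref * rho / d3, pref * dz / d3


def _assemble_stiffness(grid: AxisymGrid) -> sp.csr_matrix:
    """P1 stiffness ∫ ∇u·∇v ρ dA with centroid ρ weighting."""
    tri = grid.triangles
    p = grid.nodes[tri]  # (m, 3, 2)
    x = p[..., 0]
    y = p[..., 1]
    # gradients of barycentric basis functions
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    area = 0.5 * np.abs(area2)
    rho_bar = x.mean(axis=1)
    scale = rho_bar / (4.0 * area)
    ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) * scale[
        :, None, None
    ]
    ii = np.repeat(tri, 3, axis=1).ravel()
    jj = np.tile(tri, (1, 3)).ravel()
    n = len(grid.nodes)
    return sp.coo_matrix((ke.ravel(), (ii, jj)), shape=(n, n)).tocsr()


def _edge_mass(grid: AxisymGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge 2×2 mass matrices ∫ φiφj ρ dl on the surface edges."""
    e = grid.surface_edges
    p0 = grid.nodes[e[:, 0]]
    p1 = grid.nodes[e[:, 1]]
    l = np.linalg.norm(p1 - p0, axis=1)
    r0 = p0[:, 0]
    r1 = p1[:, 0]
    m = np.empty((len(e), 2, 2))
    m[:, 0, 0] = l * (3 * r0 + r1) / 12.0
    m[:, 0, 1] = m[:, 1, 0] = l * (r0 + r1) / 12.0
    m[:, 1, 1] = l * (r0 + 3 * r1) / 12.0
    return m, l


def solve(
    g: CellGeometry,
    bc: str = "dirichlet",
    kon: float | None = None,
    D: float = 1.0,
    q: float = 1.0,
    n_s: int = 200,
    n_t: int = 400,
    grid: AxisymGrid | None = None,
) -> GridSolution:
    """Solve the steady capture problem on shape ``g``.

    ``bc`` is "dirichlet" (perfect absorption) or "robin" (reactive
    surface with reactivity ``kon`` in µm/s and diffusivity ``D``).
    ``kon = 0`` is the reflecting limit: with a recycling (conserved)
    protein pool the steady state is a uniform concentration, returned
    directly as a flagged uniform solution.
    """
    if bc not in ("dirichlet", "robin"):
        raise ValueError("bc must be 'dirichlet' or 'robin'")
    if bc == "robin":
        if kon is None or kon < 0:
            raise ValueError("robin BC requires kon >= 0")
        if D <= 0:
            raise ValueError("D must be positive")
    if grid is None:
        grid = build_grid(g, n_s, n_t)
    r0_z = g.polar_extent - g.epsilon

    if bc == "robin" and kon == 0.0:
        c = np.ones(len(grid.nodes))
        return GridSolution(grid, g, c, c * 0, q, "uniform", 0.0, D, 0.0, 0.0)

    K = _assemble_stiffness(grid)
    n = len(grid.nodes)
    f = np.zeros(n)
    rho_n = grid.nodes[:, 0]
    z_n = grid.nodes[:, 1]
    G_nodes = _greens(q, r0_z, rho_n, z_n)

    if bc == "dirichlet":
        fixed = grid.boundary_nodes
        u_fixed = -G_nodes[fixed]
        free = np.setdiff1d(np.arange(n), fixed)
        ub = np.zeros(n)
        ub[fixed] = u_fixed
        rhs = f - K @ ub
        K_ff = K[free][:, free]
        u = ub.copy()
        u[free] = spla.spsolve(K_ff.tocsc(), rhs[free])
        residual = float(
            np.linalg.norm(K_ff @ u[free] - rhs[free])
            / max(np.linalg.norm(rhs[free]), 1e-300)
        )
    else:
        kD = kon / D
        m_e, _ = _edge_mass(grid)
        e = grid.surface_edges
        # Robin data h = (kon/D) G + ∂G/∂n at the edge endpoints, with
        # the edge's outward normal
        rows_i, cols_j, vals = [], [], []
        for a in range(2):
            for bcol in range(2):
                rows_i.append(e[:, a])
                cols_j.append(e[:, bcol])
                vals.append(kD * m_e[:, a, bcol])
        K = K + sp.coo_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows_i), np.concatenate(cols_j)),
            ),
            shape=(n, n),
        ).tocsr()
        # edge load: f_edge = −M_edge @ h (h at both endpoints)
        na = grid.surface_normals
        for a in (0, 1):
            ga_r, ga_z = _greens_grad(
                q, r0_z, grid.nodes[e[:, a], 0], grid.nodes[e[:, a], 1]
            )
            h = kD * G_nodes[e[:, a]] + ga_r * na[:, 0] + ga_z * na[:, 1]
            for brow in (0, 1):
                np.add.at(f, e[:, brow], -m_e[:, brow, a] * h)
        u = spla.spsolve(K.tocsc(), f)
        residual = float(
            np.linalg.norm(K @ u - f) / max(np.linalg.norm(f), 1e-300)
        )

    c = G_nodes + u
    sol = GridSolution(
        grid, g, c, u, q, bc, kon if bc == "robin" else None, D, residual, 0.0
    )
    sol.gauss_defect = _gauss_defect(sol)
    return sol


def _gauss_defect(sol: GridSolution) -> float:
    """|total surface capture flux − q| / q.

    The flux of the Green's term through the closed surface is exactly
    −q (point source inside), so Gauss consistency reduces to the
    surface flux of the harmonic remainder u vanishing (Dirichlet), or
    to the total Robin uptake ∮ (kon/D)·c dS equalling q (Robin). The
    Dirichlet flux uses area-weighted recovered nodal gradients of u,
    which are superconvergent on this structured mesh.
    """
    grid = sol.grid
    if sol.bc == "robin":
        kD = sol.kon / sol.D
        m_e, _ = _edge_mass(grid)
        e = grid.surface_edges
        uptake = 0.0
        for a in (0, 1):
            for brow in (0, 1):
                uptake += np.sum(m_e[:, brow, a] * sol.c[e[:, a]])
        return abs(2 * np.pi * kD * uptake - sol.q) / sol.q

    # Dirichlet: second-order one-sided normal derivative of c at the
    # surface, sampling the interpolated solution along the exact
    # inward normal; ∂c/∂n integrates to −q over the closed surface.
    g = sol.geometry
    interp = _LogicalInterp(sol)
    flux = 0.0
    for edge, nrm in zip(grid.surface_edges, grid.surface_normals):
        p0, p1 = grid.nodes[edge[0]], grid.nodes[edge[1]]
        l = float(np.hypot(*(p1 - p0)))
        rho_bar = 0.5 * (p0[0] + p1[0])
        mid = 0.5 * (p0 + p1)
        # pull the chord midpoint onto the surface along the radial ray
        sp = _project_to_surface(g, mid)
        # meridian-plane inward normal at azimuth 0: (ρ, z) components
        n_in = geo.inward_normal(g, np.array([sp[0], 0.0, sp[1]]))
        n2 = np.array([n_in[0], n_in[2]])
        delta = 0.5 * l + 1e-3 * g.polar_extent / len(grid.z_rows)
        c0 = 0.0  # Dirichlet surface value
        c1 = interp(sp + delta * n2)
        c2 = interp(sp + 2 * delta * n2)
        dcdn_in = (-3 * c0 + 4 * c1 - c2) / (2 * delta)
        flux += -dcdn_in * l * rho_bar  # ∂c/∂n_out = −∂c/∂n_in
    return abs(2 * np.pi * flux + sol.q) / sol.q


def _project_to_surface(g: CellGeometry, p2: np.ndarray) -> np.ndarray:
    """Project a meridian point (ρ, z) near the surface onto it."""
    rho, z = p2
    if g.shape == "cylinder":
        if abs(abs(z) - g.L) < abs(rho - g.R):
            return np.array([rho, math.copysign(g.L, z)])
        return np.array([g.R, z])
    az = g.a if g.shape == "spheroid" else g.R
    t = 1.0 / math.sqrt((rho / g.R) ** 2 + (z / az) ** 2)
    return np.array([rho * t, z * t])


class _LogicalInterp:
    """Bilinear interpolation of nodal c in mapped (z, s) coordinates."""

    def __init__(self, sol: GridSolution):
        grid = sol.grid
        g = sol.geometry
        self.g = g
        self.z_rows = grid.z_rows  # descending
        nt1, ns1 = grid.logical.shape
        self.vals = sol.c[grid.logical]  # (n_t+1, n_s+1), pole rows constant
        self.s = np.linspace(0.0, 1.0, ns1)

    def __call__(self, p2: np.ndarray) -> float:
        rho, z = p2
        g = self.g
        ext = g.polar_extent
        z = float(np.clip(z, -ext, ext))
        rho_z = geo.cross_section_radius(g, z)
        s = 0.0 if rho_z <= 0 else min(rho / rho_z, 1.0)
        zr = self.z_rows
        j = int(np.clip(np.searchsorted(-zr, -z) - 1, 0, len(zr) - 2))
        tz = (zr[j] - z) / (zr[j] - zr[j + 1])
        i = int(np.clip(np.searchsorted(self.s, s) - 1, 0, len(self.s) - 2))
        ts = (s - self.s[i]) / (self.s[i + 1] - self.s[i])
        v = self.vals
        return float(
            (1 - tz) * ((1 - ts) * v[j, i] + ts * v[j, i + 1])
            + tz * ((1 - ts) * v[j + 1, i] + ts * v[j + 1, i + 1])
        )


def row_profile(sol: GridSolution) -> tuple[np.ndarray, np.ndarray]:
    """Disc-averaged C(z) on the mesh rows (ascending z)."""
    grid = sol.grid
    zs, cs = [], []
    for row, zj in zip(grid.rows, grid.z_rows):
        if len(row) == 1:
            zs.append(zj)
            cs.append(sol.c[row[0]])
            continue
        rho = grid.nodes[row, 0]
        vals = sol.c[row]
        num = np.trapezoid(vals * rho, rho)
        den = np.trapezoid(rho, rho)
        zs.append(zj)
        cs.append(num / den)
    zs = np.asarray(zs)[::-1]
    cs = np.asarray(cs)[::-1]
    return zs, cs


def axial_profile(sol: GridSolution, n_bins: int = 50) -> ConcentrationProfile:
    """Binned axial profile with volume-average c0."""
    g = sol.geometry
    if sol.bc == "uniform":
        ext = g.polar_extent
        edges = np.linspace(-ext, ext, n_bins + 1)
        vols = _slice_volumes(g, edges)
        return ConcentrationProfile(
            z_centers=0.5 * (edges[:-1] + edges[1:]),
            values=np.ones(n_bins),
            c0=1.0,
            z_anterior=ext,
            bin_volumes=vols,
            metadata={"source": "oracle", "bc": "uniform", "shape": g.shape,
                      "R": g.R, "a": g.a, "L": g.L},
        )
    zs, cs = row_profile(sol)
    # clip the O(discretization) negative undershoot near the surface
    cs = np.maximum(cs, 0.0)
    interp = lambda z: np.interp(z, zs, cs)
    # volume-average c0 by trapezoid over the rows
    areas = np.pi * np.asarray(
        [geo.cross_section_radius(g, float(np.clip(z, -g.polar_extent, g.polar_extent))) ** 2 for z in zs]
    )
    c0 = float(np.trapezoid(cs * areas, zs) / geo.volume(g))
    prof = binned_profile_from_function(
        g, interp, n_bins, "oracle", c0,
        {"bc": sol.bc, "kon": sol.kon, "D": sol.D, "q": sol.q,
         "gauss_defect": sol.gauss_defect},
    )
    return prof


def _slice_volumes(g: CellGeometry, edges: np.ndarray) -> np.ndarray:
    def cum(z):
        if g.shape == "sphere":
            return np.pi * (g.R**2 * z - z**3 / 3.0)
        if g.shape == "cylinder":
            return np.pi * g.R**2 * z
        return np.pi * g.R**2 * (z - z**3 / (3.0 * g.a**2))
    return cum(edges[1:]) - cum(edges[:-1])
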