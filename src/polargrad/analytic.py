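"""Closed-form steady-state solutions of the polar transport model.

In steady state the cytoplasmic concentration obeys the Poisson
equation ∇²c = −q δ(r − r0) with q = j/D, where j is the protein
current delivered at the release point r0 just inside the anterior
pole, and with c = 0 on the cell surface for a perfectly absorbing
cortex. This is the electrostatics problem of a point charge inside a
grounded conductor:

* sphere — solved exactly by an image charge: the source q at
  r0 = (0, 0, b), b = R − ε, is mirrored by a charge −(R/b)q at
  (0, 0, R²/b);
* cylinder — solved by an eigenfunction expansion in Bessel functions
  J₀(αₙ ρ/R); the slowest axial mode decays over λ = R/α₁ with
  α₁ ≈ 2.405 the first zero of J₀, so the gradient's decay length is
  set by the radius alone, independent of the cylinder length.

The classic diffusion–degradation exponential gradient is included as
the reference model the polar transport mechanism is contrasted with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0, j1, jn_zeros

__all__ = [
    "SphereSolution",
    "CylinderSeries",
    "ReferenceExponential",
    "cylinder_decay_length",
    "diffusion_degradation_profile",
    "sphere_profile",
    "cylinder_profile",
]


# ------------------------------------------------------------- sphere

@dataclass(frozen=True)
class SphereSolution:
    """Image-charge solution for a sphere with absorbing surface.

    Source strength ``q`` sits on the axis at radius ``b = R − ε``; the
    image of strength −(R/b)·q sits at ``a_img = R²/b`` outside.
    """

    R: float
    epsilon: float
    q: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < self.R:
            raise ValueError("need 0 < epsilon < R")

    @property
    def b(self) -> float:
        return self.R - self.epsilon

    @property
    def a_img(self) -> float:
        return self.R**2 / self.b

    def concentration(self, r) -> np.ndarray | float:
        """Point concentration c(r) inside the sphere.

        c(r) = q/(4π|r−r0|) − (R/b)·q/(4π|r−r_out|) with r0 = (0,0,b)
        and r_out = (0,0,R²/b). Vanishes on |r| = R; singular at r0.
        """
        pts = np.atleast_2d(np.asarray(r, dtype=float))
        r0 = np.array([0.0, 0.0, self.b])
        r_out = np.array([0.0, 0.0, self.a_img])
        d0 = np.linalg.norm(pts - r0, axis=1)
        if np.any(d0 == 0):
            raise ValueError("concentration is singular at the release point")
        d1 = np.linalg.norm(pts - r_out, axis=1)
        c = self.q / (4 * np.pi * d0) - (self.R / self.b) * self.q / (4 * np.pi * d1)
        return float(c[0]) if np.asarray(r).ndim == 1 else c

    def axial_profile(self, z) -> np.ndarray | float:
        """Disc-averaged concentration C(z) over the cross section at z.

        The average of a Coulomb term q/(4π|r − (0,0,z_s)|) over the
        disc of radius ρ_m(z) = √(R²−z²) is
        q/(2ρ_m²)·[√(ρ_m² + (z−z_s)²) − |z−z_s|]; applying it to the
        source and its image gives the closed form.
        """
        z_arr = np.atleast_1d(np.asarray(z, dtype=float))
        if np.any(np.abs(z_arr) >= self.R):
            raise ValueError("axial profile defined for |z| < R")
        rm2 = self.R**2 - z_arr**2

        def disc_avg(z_s, Q):
            # disc average of Q/(4π|r − (0,0,z_s)|) over radius √rm2
            return (
                Q
                / (2 * np.pi * rm2)
                * (np.sqrt(rm2 + (z_arr - z_s) ** 2) - np.abs(z_arr - z_s))
            )

        c = disc_avg(self.b, self.q) + disc_avg(
            self.a_img, -(self.R / self.b) * self.q
        )
        return float(c[0]) if np.asarray(z).ndim == 0 else c

    def mean_concentration(self) -> float:
        """Volume-average c0 = q/(8πR)·(1 − b²/R²)."""
        return self.q / (8 * np.pi * self.R) * (1.0 - self.b**2 / self.R**2)

    def normalized_axial(self, z):
        return self.axial_profile(z) / self.mean_concentration()


# ----------------------------------------------------------- cylinder

def cylinder_decay_length(R: float) -> float:
    """Decay length λ = R/α₁, α₁ the first positive zero of J₀.

    α₁ is computed by root-finding at machine precision (≈2.404826),
    so λ(R=10) ≈ 4.1583 µm, independent of the cylinder length.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    alpha1 = float(jn_zeros(0, 1)[0])
    return R / alpha1


@dataclass(frozen=True)
class CylinderSeries:
    """Bessel eigenfunction expansion for a cylinder, radius R and
    half-length L (cell spans −L ≤ z ≤ L), with c = 0 on the lateral
    wall and both end caps and the source on the axis at z0 = L − ε.

    The Green's-function expansion is
        c(ρ, z) = Σₙ q/(πR² J₁(αₙ)²) · gₙ(z, z0) · J₀(αₙ ρ/R),
        gₙ = sinh(kₙ(L+z_<)) sinh(kₙ(L−z_>)) / (kₙ sinh(2kₙL)),
    with kₙ = αₙ/R. Below the source (z < z0) the n = 1 term dominates
    once e^{2L/λ} ≫ 1, giving the leading form ∝ J₀(ρ/λ) sinh((L+z)/λ).
    """

    R: float
    L: float
    epsilon: float
    n_terms: int = 40
    q: float = 1.0
    roots: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.R <= 0 or self.L <= 0:
            raise ValueError("R and L must be positive")
        if not 0 < self.epsilon < self.L:
            raise ValueError("need 0 < epsilon < L")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        object.__setattr__(self, "roots", jn_zeros(0, self.n_terms))

    @property
    def z0(self) -> float:
        return self.L - self.epsilon

    @property
    def decay_length(self) -> float:
        return self.R / float(self.roots[0])

    def _check_domain(self, rho, z):
        if np.any(np.asarray(rho) > self.R * (1 + 1e-12)) or np.any(
            np.abs(np.asarray(z)) > self.L * (1 + 1e-12)
        ):
            raise ValueError("(rho, z) outside the cylinder")

    def _g(self, k: float, z: np.ndarray) -> np.ndarray:
        z_lo = np.minimum(z, self.z0)
        z_hi = np.maximum(z, self.z0)
        # sinh ratios computed with exponentials scaled to avoid overflow
        with np.errstate(over="ignore", invalid="ignore"):
            num = np.sinh(k * (self.L + z_lo)) * np.sinh(k * (self.L - z_hi))
            den = k * np.sinh(2 * k * self.L)
            out = num / den
        if not np.all(np.isfinite(out)):
            # large-argument form: sinh(x) ≈ e^x/2
            loga = _log_sinh(k * (self.L + z_lo)) + _log_sinh(k * (self.L - z_hi))
            logb = math.log(k) + _log_sinh_scalar(2 * k * self.L)
            out = np.exp(loga - logb)
        return out

    def concentration(self, rho, z) -> np.ndarray | float:
        """Full series c(ρ, z)."""
        rho_a = np.atleast_1d(np.asarray(rho, dtype=float))
        z_a = np.atleast_1d(np.asarray(z, dtype=float))
        self._check_domain(rho_a, z_a)
        rho_a, z_a = np.broadcast_arrays(rho_a, z_a)
        c = np.zeros(rho_a.shape)
        for alpha in self.roots:
            k = alpha / self.R
            coef = self.q / (np.pi * self.R**2 * j1(alpha) ** 2)
            c += coef * self._g(k, z_a) * j0(alpha * rho_a / self.R)
        if np.asarray(rho).ndim == 0 and np.asarray(z).ndim == 0:
            return float(c.ravel()[0])
        return c

    def leading_term(self, rho, z, n_cyto: float | None = None):
        """First-mode approximation (1/Z)·J₀(ρ/λ)·sinh((L+z)/λ).

        Valid below the source when e^{2L/λ} ≫ 1; warns when
        2L/λ < 3. If ``n_cyto`` is given, Z is chosen so the
        cytoplasmic volume integral equals that total number;
        otherwise Z matches the full-series n = 1 amplitude.
        """
        lam = self.decay_length
        if 2 * self.L / lam < 3:
            warnings.warn(
                "leading-term approximation dubious: 2L/lambda < 3", stacklevel=2
            )
        rho_a = np.asarray(rho, dtype=float)
        z_a = np.asarray(z, dtype=float)
        self._check_domain(rho_a, z_a)
        shape = j0(rho_a / lam) * np.sinh((self.L + z_a) / lam)
        if n_cyto is not None:
            # ∫ J0(ρ/λ) sinh((L+z)/λ) ρ dρ dφ dz over the cylinder
            alpha1 = float(self.roots[0])
            integral = (
                2 * np.pi * self.R**2 * j1(alpha1) / alpha1
                * lam * (np.cosh(2 * self.L / lam) - 1.0)
            )
            Z = integral / n_cyto
        else:
            alpha1 = float(self.roots[0])
            k = alpha1 / self.R
            amp = (
                self.q
                / (np.pi * self.R**2 * j1(alpha1) ** 2)
                * np.sinh(k * (self.L - self.z0))
                / (k * np.sinh(2 * k * self.L))
            )
            Z = 1.0 / amp
        return shape / Z

    def axial_profile(self, z) -> np.ndarray | float:
        """Disc-averaged C(z): the J₀ factor averages to 2J₁(αₙ)/αₙ."""
        z_a = np.atleast_1d(np.asarray(z, dtype=float))
        self._check_domain(0.0, z_a)
        c = np.zeros(z_a.shape)
        for alpha in self.roots:
            k = alpha / self.R
            coef = 2.0 * self.q / (np.pi * self.R**2 * alpha * j1(alpha))
            c += coef * self._g(k, z_a)
        return float(c.ravel()[0]) if np.asarray(z).ndim == 0 else c

    def mean_concentration(self) -> float:
        """Volume average c0 = (1/2L)·∫ C(z) dz, in closed form.

        ∫gₙ dz = [sinh(kd₋)(cosh(kd₊)−1) + sinh(kd₊)(cosh(kd₋)−1)]
                 / (k² sinh(2kL)), with d± = L ± z0; evaluated in log
        space to stay finite for high modes.
        """
        total = 0.0
        for alpha in self.roots:
            k = alpha / self.R
            coef = 2.0 * self.q / (np.pi * self.R**2 * alpha * j1(alpha))
            dm = k * (self.L - self.z0)
            dp = k * (self.L + self.z0)
            denom = 2.0 * math.log(k) + _log_sinh_scalar(2 * k * self.L)
            integral = (
                math.exp(_log_sinh_scalar(dm) + _log_cosh_scalar(dp) - denom)
                - math.exp(_log_sinh_scalar(dm) - denom)
                + math.exp(_log_sinh_scalar(dp) + _log_cosh_scalar(dm) - denom)
                - math.exp(_log_sinh_scalar(dp) - denom)
            )
            total += coef * integral
        return total / (2 * self.L)

    def normalized_axial(self, z):
        return self.axial_profile(z) / self.mean_concentration()


def _log_sinh(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    small = x < 30
    with np.errstate(divide="ignore"):  # log(sinh(0)) = −inf is intended
        out[small] = np.log(np.sinh(x[small]))
    out[~small] = x[~small] - math.log(2.0)
    return out


def _log_sinh_scalar(x: float) -> float:
    return math.log(math.sinh(x)) if x < 30 else x - math.log(2.0)


def _log_cosh_scalar(x: float) -> float:
    return math.log(math.cosh(x)) if x < 30 else x - math.log(2.0)


# ---------------------------------------------- diffusion–degradation

@dataclass(frozen=True)
class ReferenceExponential:
    """Steady state of the diffusion–degradation model: c0·e^{−z/λ}."""

    c0: float
    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("decay length must be positive")

    def __call__(self, z):
        return self.c0 * np.exp(-np.asarray(z, dtype=float) / self.lam)


def diffusion_degradation_profile(c0: float, D: float, tau: float, z):
    """c(z) = c0·exp(−z/λ) with λ = √(D·τ).

    The reference gradient of a source at z = 0 with diffusion D and
    first-order degradation over lifetime τ; its decay length depends
    on kinetic parameters, unlike the polar transport gradient.
    """
    if D <= 0 or tau <= 0:
        raise ValueError("D and tau must be positive")
    lam = math.sqrt(D * tau)
    return ReferenceExponential(c0, lam)(z)


# -------------------------------------------------- profile builders

def sphere_profile(R: float, epsilon: float | None = None, q: float = 1.0,
                   n_bins: int = 50):
    """Binned :class:`ConcentrationProfile` of the sphere closed form."""
    from .geometry import CellGeometry
    from .profiles import binned_profile_from_function

    g = CellGeometry.sphere(R, epsilon)
    sol = SphereSolution(R, g.epsilon, q)
    return binned_profile_from_function(
        g, sol.axial_profile, n_bins, "analytic", sol.mean_concentration(),
        {"q": q}, breakpoints=(sol.b, ),
    )


def cylinder_profile(R: float, L: float, epsilon: float | None = None,
                     q: float = 1.0, n_terms: int = 40, n_bins: int = 50):
    """Binned :class:`ConcentrationProfile` of the cylinder series."""
    from .geometry import CellGeometry
    from .profiles import binned_profile_from_function

    g = CellGeometry.cylinder(R, L, epsilon)
    series = CylinderSeries(R, L, g.epsilon, n_terms, q)
    return binned_profile_from_function(
        g, series.axial_profile, n_bins, "analytic",
        series.mean_concentration(), {"q": q, "n_terms": n_terms},
        breakpoints=(series.z0, ),
    )
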