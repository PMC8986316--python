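"""Order-of-magnitude calculators for cortical-transport gradients.

Back-of-the-envelope numbers for the budding yeast actin-cable system:
the monomer flux generated by treadmilling cables, the steady-state
pole-to-pole concentration difference that flux must be balanced by,
the dimensionless capture efficiency kon·R/D that decides whether the
gradient is in the scale-invariant regime, and the number of cortical
motors needed to reach that regime.

All calculators return full-precision values; round for comparison
with one-significant-figure literature numbers yourself (or via the
CLI's ``--sigfigs``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TreadmillParams",
    "treadmilling_flux",
    "pole_concentration_difference",
    "capture_efficiency",
    "motor_count_threshold",
    "UM3_PER_UM",
]

#: number density (µm⁻³) corresponding to 1 µM: N_A × 10⁻⁶ mol/L × 10⁻¹⁵ L/µm³
UM3_PER_UM = 6.02214e23 * 1e-6 * 1e-15  # = 602.214 µm⁻³ per µM


@dataclass(frozen=True)
class TreadmillParams:
    """Inputs of the actin-cable treadmilling estimate.

    Defaults are the standard yeast numbers: cables extend at about
    0.5 µm/s, there are about 10 cables per cell of about 5 filaments
    each, and an actin filament holds about 300 monomers per µm.
    """

    extension_rate: float = 0.5      # µm/s
    n_cables: int = 10
    filaments_per_cable: int = 5
    monomers_per_micron: float = 300.0   # 1/µm
    D: float = 1.0                   # monomer diffusivity, µm²/s
    R: float = 2.0                   # cell radius, µm

    def __post_init__(self) -> None:
        if min(self.extension_rate, self.n_cables, self.filaments_per_cable,
               self.monomers_per_micron, self.D, self.R) < 0:
            raise ValueError("parameters must be nonnegative")


def treadmilling_flux(p: TreadmillParams) -> float:
    """Monomer turnover rate J of the cable system (monomers/s).

    J = extension rate × cables × filaments per cable × monomers/µm;
    with the default parameters this is 7500 ≈ 8×10³ monomers/s.
    """
    return (
        p.extension_rate
        * p.n_cables
        * p.filaments_per_cable
        * p.monomers_per_micron
    )


@dataclass(frozen=True)
class ConcentrationDifference:
    number_density: float   # µm⁻³
    molar: float            # µM


def pole_concentration_difference(J: float, D: float, R: float) -> ConcentrationDifference:
    """Pole-to-pole concentration difference balancing a flux J.

    In steady state the directed monomer flux J toward one pole is
    balanced by the diffusive return flux, estimated as
    D·Δc/(2R)·πR². Solving for Δc gives Δc = 2J/(π·D·R), converted to
    molar units via 1 µM = 602.214 µm⁻³.
    """
    if D <= 0 or R <= 0:
        raise ValueError("D and R must be positive")
    if J < 0:
        raise ValueError("J must be nonnegative")
    dc = 2.0 * J / (math.pi * D * R)
    return ConcentrationDifference(number_density=dc, molar=dc / UM3_PER_UM)


def capture_efficiency(kon: float, R: float, D: float) -> float:
    """Dimensionless capture rate kon·R/D.

    Values ≫ 1 put the gradient in the perfectly absorbing,
    scale-invariant regime; values ≪ 1 approach the reflecting wall
    and the gradient flattens and loses scaling.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if kon < 0 or R < 0:
        raise ValueError("kon and R must be nonnegative")
    return kon * R / D


@dataclass(frozen=True)
class MotorThreshold:
    threshold: float       # minimum motors for efficient capture, ≈ R/b
    full_coverage: float   # motors to tile the whole surface, ≈ 4πR²/b²

    @property
    def fraction_needed(self) -> float:
        return self.threshold / self.full_coverage


def motor_count_threshold(R: float, motor_size: float) -> MotorThreshold:
    """Cortical motor count needed for efficient capture.

    Diffusing proteins find surface absorbers efficiently once the
    number of motors exceeds ≈ R/b (b the motor size) — a tiny
    fraction b/(4πR) of the ≈ 4πR²/b² motors that would tile the
    surface completely.
    """
    if R <= 0 or motor_size <= 0:
        raise ValueError("R and motor_size must be positive")
    return MotorThreshold(
        threshold=R / motor_size,
        full_coverage=4.0 * math.pi * R**2 / motor_size**2,
    )
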