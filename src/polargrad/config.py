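"""Structured run configuration (YAML) with strict validation.

A run config has four blocks — geometry, physics, simulation, output —
mirroring the library's objects. Unknown keys are rejected so typos
fail loudly. ``kon: null`` means a perfectly absorbing surface and
``t_bound: null`` means no detachment (the corresponding rate
limits kon → ∞ and γ → 0).
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .brownian import SimConfig
from .geometry import CellGeometry

__all__ = ["RunConfig", "load_config"]


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shape: str
    R: float = Field(gt=0)
    a: float | None = None
    L: float | None = None
    epsilon_fraction: float = Field(default=0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self):
        if self.shape not in ("sphere", "cylinder", "spheroid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "spheroid":
            if self.a is None or self.a < self.R:
                raise ValueError("spheroid requires a >= R")
        if self.shape == "cylinder" and (self.L is None or self.L <= 0):
            raise ValueError("cylinder requires L > 0")
        return self

    def build(self) -> CellGeometry:
        ext = {"sphere": self.R, "cylinder": self.L, "spheroid": self.a}[self.shape]
        return CellGeometry(
            self.shape,
            self.R,
            a=self.a or 0.0,
            L=self.L or 0.0,
            epsilon=self.epsilon_fraction * ext,
        )


class PhysicsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    D: float = Field(default=1.0, gt=0)
    v: float = Field(default=1.0, gt=0)
    kon: float | None = Field(default=None, ge=0)      # None → perfect absorption
    t_bound: float | None = Field(default=None, ge=0)  # None → no detachment


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    N: int = Field(default=1000, ge=1)
    dt: float = Field(default=1e-3, gt=0)
    T_total: float = Field(default=600.0, gt=0)
    burn_in: float | None = Field(default=None, ge=0)
    n_bins: int = Field(default=50, ge=10)
    seed: int = 0
    snapshot_interval: float = Field(default=0.5, gt=0)


class OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "polargrad_out"
    formats: list[str] = Field(default_factory=lambda: ["csv", "json"])


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryBlock
    physics: PhysicsBlock = Field(default_factory=PhysicsBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    def build_geometry(self) -> CellGeometry:
        return self.geometry.build()

    def build_sim_config(self, seed: int | None = None) -> SimConfig:
        p, s = self.physics, self.simulation
        return SimConfig(
            D=p.D,
            v=p.v,
            dt=s.dt,
            N=s.N,
            kon=math.inf if p.kon is None else p.kon,
            t_bound=math.inf if p.t_bound is None else p.t_bound,
            T_total=s.T_total,
            burn_in=s.burn_in,
            n_bins=s.n_bins,
            seed=s.seed if seed is None else seed,
            snapshot_interval=s.snapshot_interval,
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    return RunConfig.model_validate(data)
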