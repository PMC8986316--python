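"""Imperfect transport: detachment flattens the gradient.

Simulates spheres in which a surface-bound protein can fall off the
cortical transport at rate γ = 1/t_bound before reaching the pole.
As t_bound drops below the transit time (~R/v seconds) the gradient
flattens toward the uniform reflecting-wall state, while the release
bump and anterior accumulation fade. The anterior/posterior contrast
printed below decreases monotonically with t_bound.

Runtime ~3 minutes at these reduced recording windows.
"""

import math

import numpy as np

from polargrad import CellGeometry, SimConfig, run, normalize

g = CellGeometry.sphere(10)

def contrast(p):
    d = p.distance_from_pole
    anterior = p.values[(d > 1.0) & (d < 7.0)].mean()
    posterior = p.values[d > 13.0].mean()
    return anterior / posterior

print("  t_bound (s)   anterior/posterior contrast   surface fraction")
for tb in (math.inf, 1.0, 0.1, 0.001):
    cfg = SimConfig(T_total=250.0, burn_in=70.0, seed=3, t_bound=tb)
    res = run(cfg, g)
    p = normalize(res.profile)
    print(f"  {tb!s:>11}   {contrast(p):27.2f}   {res.surface_fraction:.3f}")

print("\nWith t_bound >> R/v nearly every captured protein reaches the pole and")
print("the full gradient forms; with t_bound -> 0 capture is undone immediately,")
print("the wall acts reflecting, and the contrast drops to ~1 (no gradient).")
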