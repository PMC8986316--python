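"""Steady gradient in a spherical cell: simulation vs closed form.

Runs the particle simulation (1000 proteins, D = 1 µm²/s, v = 1 µm/s,
perfectly absorbing cortex) in a sphere of radius 10 µm and compares
the steady-state normalized axial profile C(z)/c0 with the exact
image-charge solution. The two should agree within counting noise:
the printed reduced chi-square is ≈ 1 when they do.

A short recording window is used here so the example finishes in about
a minute; double T_total/burn_in for tighter error bars.
"""

import numpy as np

from polargrad import CellGeometry, SimConfig, run, normalize
from polargrad.analytic import SphereSolution, sphere_profile

g = CellGeometry.sphere(10)  # release offset ε defaults to 0.05·R
cfg = SimConfig(T_total=300.0, burn_in=80.0, seed=0, snapshot_interval=1.0)
res = run(cfg, g)

sim = normalize(res.profile)
exact = SphereSolution(g.R, g.epsilon)

print(f"mean cytoplasmic concentration c0 = {res.c0:.4f} /um^3")
print(f"surface-bound fraction            = {res.surface_fraction:.3f}")
print(f"delivery current at the pole      = {res.delivered_current:.1f} /s")
print()
print("   z (um)   C/c0 sim   C/c0 exact")
for i in range(2, 50, 6):
    z = sim.z_centers[i]
    print(f"  {z:7.1f}   {sim.values[i]:8.3f}   {exact.normalized_axial(z):8.3f}")

# reduced chi-square of binned counts against the closed form
ana = sphere_profile(g.R, g.epsilon)
p = ana.values * ana.bin_volumes
p /= p.sum()
expected = res.profile.counts.sum() * p
chi2 = np.sum((res.profile.counts - expected) ** 2 / expected)
print(f"\nreduced chi-square vs closed form: {chi2 / (len(p) - 1):.2f}")
print("(~1 means the simulated gradient is statistically identical to the")
print(" image-charge steady state; the excess near z = 9.5 um is the release bump)")
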