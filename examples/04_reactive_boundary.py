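"""Imperfect capture: the dimensionless rate kon·R/D decides scaling.

Solves the steady capture problem with a reactive (Robin) surface
condition −D ∂c/∂n = kon·c on spheres of different radius using the
grid solver, at kon = 0.1 µm/s (capture efficiency kon·R/D of order 1)
and kon = 1000 µm/s (effectively perfect absorption). With weak
capture the rescaled profiles no longer coincide — scale invariance is
lost — while strong capture reproduces the absorbing-limit collapse.
"""

import numpy as np

from polargrad import CellGeometry, collapse_metric, normalize
from polargrad.estimates import capture_efficiency
from polargrad import oracle

D = 1.0
for kon in (0.1, 1000.0):
    profs = []
    for R in (5.0, 10.0, 20.0):
        g = CellGeometry.sphere(R)
        sol = oracle.solve(g, "robin", kon=kon, D=D, n_s=120, n_t=240)
        profs.append(normalize(oracle.axial_profile(sol)))
        print(
            f"kon = {kon:6.1f}  R = {R:4.0f}  kon*R/D = {capture_efficiency(kon, R, D):7.1f}"
            f"   flux balance defect = {sol.gauss_defect:.1e}"
        )
    m = collapse_metric(profs, [5.0, 10.0, 20.0])
    print(f"  -> collapse metric across radii: {m:.3f}\n")

print("kon = 0.1 (kon*R/D ~ 1): metric of order 1 — the rescaled gradients")
print("disagree, scaling is absent. kon = 1000 (kon*R/D >> 1): the metric")
print("drops to the absorbing-limit value — scaling is restored. Efficient")
print("capture needs only ~R/b motors (see polargrad.estimates.motor_count_threshold).")
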