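"""Scale invariance: C(z)/c0 depends only on z/R.

Builds the exact normalized sphere profiles for R = 5, 10 and 20 µm
(with the release offset scaling as 0.05·R) and prints them against
the scaled distance from the pole d/R: the three columns are
identical. The collapse metric — the largest pairwise difference
between the rescaled curves — is at float precision.
"""

import numpy as np

from polargrad import collapse_metric, normalize
from polargrad.analytic import sphere_profile

radii = (5.0, 10.0, 20.0)
profs = [normalize(sphere_profile(R, n_bins=100)) for R in radii]

print("   d/R     C/c0 (R=5)   C/c0 (R=10)   C/c0 (R=20)")
grid = np.linspace(0.15, 1.75, 9)
for x in grid:
    row = []
    for p, R in zip(profs, radii):
        d = p.distance_from_pole[::-1] / R
        row.append(np.interp(x, d, p.values[::-1]))
    print(f"  {x:5.2f}   {row[0]:10.4f}   {row[1]:10.4f}   {row[2]:10.4f}")

m = collapse_metric(profs, list(radii))
print(f"\ncollapse metric (max pairwise difference of rescaled curves): {m:.2e}")
print("A value at numerical precision means the gradient carries positional")
print("information in units of the cell radius — cells of different size read")
print("out the same relative coordinate.")
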