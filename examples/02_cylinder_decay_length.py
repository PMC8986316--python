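"""The cylinder gradient decays over λ = R/2.405, whatever the length.

Evaluates the Bessel-series steady state for cylinders of radius
10 µm and half-lengths 20, 30 and 40 µm, fits an exponential to each
axial profile, and prints the fitted decay lengths next to R/α₁
(α₁ ≈ 2.405, the first zero of J₀). The fitted λ should be within a
couple of percent of R/α₁ for every length: the cell's radius, not its
length, sets the gradient scale.
"""

from polargrad import cylinder_decay_length, fit_decay_length
from polargrad.analytic import cylinder_profile

R = 10.0
lam_theory = cylinder_decay_length(R)
print(f"R = {R} um  ->  lambda = R/alpha_1 = {lam_theory:.4f} um\n")
print("  half-length L   fitted lambda   deviation")
for L in (20.0, 30.0, 40.0):
    prof = cylinder_profile(R, L, n_bins=120)
    # fit away from the release bump (d < 2 eps) and the posterior fall-off
    fit = fit_decay_length(prof, (2 * prof.metadata["epsilon"], 2 * L - lam_theory))
    print(
        f"  {L:10.0f}      {fit.lam:8.4f} um    {100 * (fit.lam / lam_theory - 1):+.2f}%"
        f"   (r^2 = {fit.r2:.5f})"
    )
print("\nThe decay length is set by the radius alone; the cell length only")
print("extends the exponential, so the mid-cell concentration falls off")
print("as ~ exp(-2.405 L/R) as the cell elongates.")
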