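"""Order-of-magnitude numbers for the budding yeast actin-cable system.

Composes the calculators in polargrad.estimates: the monomer flux
generated by treadmilling actin cables, the pole-to-pole concentration
difference needed to return that flux by diffusion, and the number of
cortical motors required for the gradient to reach the scale-invariant
(perfect capture) regime.
"""

from polargrad.estimates import (
    TreadmillParams,
    capture_efficiency,
    motor_count_threshold,
    pole_concentration_difference,
    treadmilling_flux,
)

p = TreadmillParams()  # 0.5 um/s, 10 cables, 5 filaments, 300 monomers/um
J = treadmilling_flux(p)
dc = pole_concentration_difference(J, p.D, p.R)

print(f"cable treadmilling monomer flux J = {J:.0f} monomers/s (~8e3 at 1 s.f.)")
print(f"pole-to-pole difference  delta_c = {dc.number_density:.0f} /um^3")
print(f"                                 = {dc.molar:.2f} uM")
print("(a few uM: comparable to cellular G-actin levels, so the gradient is")
print(" physiologically visible)")
print()
for kon in (0.01, 0.1, 1.0):
    eff = capture_efficiency(kon, R=10.0, D=1.0)
    regime = "scale-invariant" if eff >= 10 else ("marginal" if eff >= 1 else "flat/no scaling")
    print(f"kon = {kon:5.2f} um/s  ->  kon*R/D = {eff:5.1f}   ({regime})")
print()
t = motor_count_threshold(R=10.0, motor_size=0.01)
print(f"motors needed for efficient capture: ~R/b = {t.threshold:.0f}")
print(f"motors to tile the whole surface:    ~4*pi*R^2/b^2 = {t.full_coverage:.2e}")
print(f"fraction of full coverage required:  {t.fraction_needed:.2e}")
print("(a vanishing fraction of surface coverage suffices for perfect capture)")
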