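# Methods

## The polar transport model

`polargrad` studies how a cell can build an intracellular protein
gradient whose *shape is set by the cell's geometry alone*. The model
couples two transport processes:

1. **Cytoplasmic diffusion.** N protein molecules diffuse freely in
   the cell body with diffusivity D.
2. **Cortical transport.** When a molecule reaches the cell surface it
   can be captured by motors moving along surface filaments and is
   then carried deterministically along the surface meridian toward
   the *anterior pole* at speed v. After a transit time d/v — d the
   path length from the capture point to the pole — it is released
   back into the cytoplasm at the release point r0, a distance ε
   inside the pole on the symmetry axis.

No molecules are created or destroyed; the total count N is conserved
exactly. In steady state the delivery current j at the pole balances
the capture flux at the surface, and the cytoplasmic concentration c
solves the Poisson problem

    ∇²c = −q δ(r − r0),   q = j/D,

with c = 0 on the surface when every encounter leads to capture. This
is the electrostatics of a point charge in a grounded conductor, which
is why the sphere admits an exact image-charge solution and the
cylinder a Bessel eigenfunction expansion. Because the boundary-value
problem contains no kinetic parameter, the *normalized* profile
C(z)/c0 depends only on relative position z/(cell size): the gradient
is scale-invariant, with decay length ∝ the cell's radius (λ = R/α₁ ≈
R/2.405 for a cylinder, α₁ the first zero of J₀). D, v and the total
protein count only set the amplitude q and the cytoplasm/surface
partition, not the shape.

Two imperfections are modeled because they break or preserve this
picture in instructive ways:

* **Imperfect capture** — a finite surface reactivity kon (µm/s)
  replaces the absorbing condition by the Robin condition
  −D ∂c/∂n = kon·c. The controlling group is the dimensionless
  capture efficiency kon·R/D: for kon·R/D ≪ 1 the wall is effectively
  reflecting, the gradient flattens and scale invariance is lost
  (the boundary condition introduces the fixed length D/kon); for
  kon·R/D ≫ 1 the absorbing limit and its scaling return.
* **Imperfect transport** — a bound molecule detaches at rate
  γ = 1/t_bound and rejoins the cytoplasm where it is. When t_bound is
  shorter than the transit time ~R/v the gradient flattens; at
  t_bound → 0 capture is undone immediately and the surface acts
  reflecting.

## Geometries

Sphere (radius R), cylinder (radius R, half-length L; the cell spans
−L ≤ z ≤ L), and prolate spheroid (equatorial radius R, polar
semi-axis a ≥ R). The anterior pole is on the +z axis. Transport path
lengths d are the exact meridian arcs: R·arccos(z/R) for the sphere
and an incomplete elliptic integral of the second kind for the
spheroid. For the cylinder the lateral-wall path is L − z (the
meridian run to the anterior rim); since nothing in the steady
cytoplasmic profile depends on transit duration (it only shifts the
surface/cytoplasm partition), end caps are treated the same way:
capture on the anterior cap transits the in-cap radius ρ, capture on
the posterior cap crosses the cap (R − ρ) and then the full lateral
wall 2L.

The release offset defaults to ε = 0.05 × (polar semi-extent) for
every shape, so that ε scales with cell size and the normalized
profile stays a function of relative position only. The profile
carries a bump within ~ε of the pole (the release point is a real
singularity of the steady state); all decay-length fits and collapse
comparisons exclude d < 2ε.

## Particle simulation

Euler–Maruyama updates with Δt = 0.001 s by default: each coordinate
receives an independent N(0, 2DΔt) increment. Defaults D = 1 µm²/s,
v = 1 µm/s, N = 1000 — typical cytoplasmic diffusion and motor speeds.

**Wall handling.** Crossings are detected at the end of the step; the
crossing point is the exact intersection of the step segment with the
surface (closed-form quadratics). With perfect absorption the particle
is captured there. Naive end-of-step detection misses excursions that
leave and re-enter within one step, which biases the wall outward by
O(√(DΔt)); we therefore add the standard Brownian-bridge correction —
a step staying inside still touches the wall with probability
exp(−h₁h₂/(DΔt)) for start/end wall distances h₁, h₂ — which removes
the leading bias and is what brings the simulated sphere profile into
χ² ≈ 1 agreement with the closed form at Δt = 0.001.

**Reactive wall.** With finite kon a wall encounter captures with
probability P = kon·√(πΔt/D) (the standard partially-absorbing-wall
calibration for end-of-step Brownian dynamics; no bridge term is
added because P is calibrated for the plain scheme). Non-captured
particles reflect specularly about the tangent plane at the crossing;
in the rare case the reflected point is still outside (strong
curvature, cylinder corners) the whole step is redrawn (counted and
reported). kon = 0 is the reflecting control.

**Detachment.** Each surface-bound particle detaches with probability
Δt/t_bound per step, re-entering the cytoplasm at its current
meridional transport position, displaced inward by one diffusion step
length √(2DΔt). The re-entry depth is a genuine modeling choice: the
continuum problem has c = 0 at an absorbing wall, so a particle
re-inserted arbitrarily close to the surface is recaptured at the same
position with probability one and detachment would have no effect at
all; a depth of one step length — the resolution of the discrete walk
— is the smallest scale at which "re-entering the cytoplasm" is
meaningful, and it reproduces both expected limits (strong flattening
for t_bound below the transit time, and the reflecting wall as
t_bound → 0, because a particle that detaches in its capture step has
made zero transport progress). Note a subtlety of any local re-entry
rule: at intermediate t_bound a capture–detach–recapture cycle
advances a particle ~v·t_bound poleward, so transport degrades
gracefully (an effective crawl) rather than switching off abruptly.

**Recording.** Profiles are time-averaged histograms of cytoplasmic
z positions on 50 equal-width slices, sampled every 0.5–1 s (longer
than the per-bin decorrelation time Δz²/D, so per-bin counting errors
are approximately Poisson). c0 is the mean cytoplasmic count divided
by the cell volume. Burn-in defaults to the very conservative
10·(polar extent)²/D; the tests and the acceptance script set explicit
burn-ins of a few slowest-relaxation times R²/(π²D) and verify
convergence via the L1 distance (< 0.05) between the normalized
profiles of the two halves of the recording window. Recording windows
of 150–600 s with N = 1000 give per-bin statistical errors of 1–3%;
these problem sizes are the package's standard study conditions.

## Analytic solutions

* **Sphere:** c(r) = q/4π|r−r0| − (R/b)q/4π|r−r_out| with b = R − ε,
  r_out = (0,0,R²/b). The axial profile C(z) is the disc average,
  derived here directly (the disc average of a Coulomb term
  Q/4π|r−rs| over radius ρm is Q[√(ρm²+Δz²) − |Δz|]/2πρm²) and
  validated against 2-D quadrature of c to 1e-6; c0 = q(1−b²/R²)/8πR,
  validated against volume quadrature.
* **Cylinder:** the Green's-function expansion
  c = Σₙ q·gₙ(z,z0)·J₀(αₙρ/R)/(πR²J₁(αₙ)²),
  gₙ = sinh(kₙ(L+z<))·sinh(kₙ(L−z>))/(kₙ sinh 2kₙL), kₙ = αₙ/R, with
  the source on the axis at z0 = L − ε and absorbing caps (consistent
  with the sinh((L+z)/λ) form of the leading mode, which vanishes at
  the posterior cap). Hyperbolic ratios are evaluated in log space for
  high modes. Bessel zeros come from SciPy's root finder, never a
  hard-coded 2.4. Truncation at 40 terms leaves transverse ringing
  only in a thin slab at the source height; outside |z − z0| > 0.5 µm
  the series matches the independent grid solver to ~0.1%.
* **Reference model:** the diffusion–degradation exponential
  c0·e^{−z/λ}, λ = √(Dτ) — the gradient whose length scale *does*
  depend on kinetics, included for contrast.

## Grid solver (numerical oracle)

An axisymmetric P1 finite-element solver on a boundary-fitted
structured mesh of the meridian half-plane: mesh rows are discs of
constant z (cosine-clustered toward the poles), nodes at s·ρ(z) with
s ∈ [0,1], pole rows collapsing to single nodes. The point source is
removed exactly by singularity subtraction (c = G + u with
G = q/4π|r−r0|); the smooth harmonic remainder u carries the
inhomogeneous Dirichlet or Robin boundary data. The Robin term is a
natural weak-form surface integral, so the curved boundary needs no
one-sided stencils; this is why a mapped-mesh FEM was chosen over the
cut-cell finite-difference alternative. Default resolution 200×400;
sparse direct solve. Verification: second-order L∞ convergence to the
sphere image-charge solution (<2% at 0.1 µm resolution), discrete
Gauss balance (total surface capture flux = q within 1%, measured by
a second-order one-sided normal derivative for Dirichlet and by
∮(kon/D)c dS for Robin), the kon → ∞ limit reproducing Dirichlet to
<1%, and exact profile coincidence for matched kon·R/D across R
(the discrete problem inherits the continuum scaling symmetry).

## Diagnostics

* **Decay length:** unweighted least squares of log C vs distance
  from the anterior pole on a window excluding the release bump
  (d < 2ε) and the posterior fall-off (within ~λ of the far pole).
* **Collapse metric:** profiles are normalized by c0, plotted against
  d/(scale), linearly interpolated onto a common grid (the bump region
  d/scale < 0.1 excluded), and the maximum absolute pairwise
  difference is returned. Zero means perfect collapse. The thresholds
  used in tests are package-defined diagnostics: exact collapses sit
  at float precision, sampling-limited simulated collapses at ~0.1–0.3
  (dominated by the steep shoulder just outside the bump), and broken
  collapses at order 1 and above. "Approximate" collapse is therefore
  operationalized as a metric at least 4× below the broken-collapse
  level measured the same way. One consequence worth stating plainly:
  with kon fixed at 1 µm/s across R ∈ {5,10,20} the Robin boundary
  layer (relative size D/kon·R) still produces absolute deviations of
  0.16–0.49 in the steep window d/R ∈ [0.2,1] — an order of magnitude
  below the weak-capture case but not below 0.05; claims of restored
  scaling at kon·R/D ~ 10 are approximate in exactly this sense.

## What the synthetic data do and do not show

All inputs are generated internally; there is no experimental data.
The particle simulator *is* the synthetic-data generator, and its
defaults are the study conditions (D = 1 µm²/s, v = 1 µm/s,
Δt = 0.001 s, N = 1000, ε = 0.05×extent). It emulates ideal
point-like, non-interacting proteins with a continuum motor field: no
crowding, no hydrodynamics, no discrete filaments or motor stepping,
no cytoplasmic flows. Passing tests show the stochastic dynamics, the
closed forms and the grid solver agree with each other under these
idealizations — they do not show that any real cell's gradient is
scale-invariant, only that the proposed mechanism produces one.

## Numerical choices and degenerate inputs

* Surface tolerance for "on surface" checks: 1e-6 × semi-axis.
* Boundary-crossing roots are closed-form; results satisfy the
  implicit surface equation to 1e-9.
* Spheroid wall distances use the first-order level-set estimate
  (exact for a = R); adequate because they only gate the bridge
  correction.
* Profile bins at the poles have near-zero volume and are noise-
  dominated in simulations; volume-weighted comparisons or interior
  masks are used where they would otherwise dominate a max-norm.
* kon = 0 in the grid solver returns the uniform profile directly (a
  pure-Neumann steady state with a source does not exist; with a
  recycling pool the physical steady state is well-mixed).
* Degenerate spheroid a = R reproduces the sphere to solver precision.

## Known limitations

* The detachment re-entry rule (depth √(2DΔt)) is one defensible
  discretization of an under-determined continuum limit; detachment
  observables at intermediate t_bound depend on it quantitatively
  (though not the t_bound → ∞ or → 0 limits, nor any perfect-capture
  result).
* The reactive-wall capture probability is first-order in √Δt;
  simulated Robin profiles carry an O(√Δt) bias that is below the
  sampling error at Δt = 0.001 but would surface at much larger steps.
* The cylinder-cap transport path is a modeling convention (see
  Geometries); it affects transit bookkeeping only.
* The leading-term cylinder formula is only meaningful when
  e^{2L/λ} ≫ 1; the code warns when 2L/λ < 3.
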