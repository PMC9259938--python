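# Methods

This note records the model equations, the parameters that matter, the
numerical design choices made where the design was genuinely open, and the
known limitations of the desk-scale configuration.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Physical model

**Geometry.** Axisymmetric (x, r) half-plane.  Aorta: radius 1 cm, length
40 cm, extended by the 15 cm outflow boundary model.  The dissected segment
spans 29 cm starting 5 cm from the inlet; the intimal septum is a
cylindrical flap at radius r_TL separating the true lumen (inner) from the
annular false lumen; 1 cm tears at both ends of the segment are the only
TL–FL communications; rigid radial caps close the FL at its two ends.  The
endograft is a rigid ring starting at the proximal end of the segment with
length λ·L_septum, sealing the proximal tear.  We take r_TL = 0.5 cm (the
FL is typically the larger channel in type B dissection; the value is a
configurable default because no measurement fixes it).  At desk resolution
the septum line is snapped to a lattice face so the endograft ring (one
solid lattice row outward of the line) seals flush against it.

**Fluid.** Incompressible single-relaxation-time D2Q9 lattice-Boltzmann
with Guo forcing.  Pressure is carried by ρ₀ (p = c_s²ρ₀); momentum uses
the constant reference density.  The cylindrical-coordinate corrections
enter as the first-order mass source h₁ = −w_i v_r/r plus an equivalent
body force F_axi = (ν ∂_r v_x / r − v_x v_r / r, ν(∂_r v_r/r − v_r/r²) −
v_r²/r) applied through the forcing channel; strain rates come from
non-equilibrium moments with one central difference for ∂_x v_r.  The form
follows from requiring the cylindrical Navier–Stokes equations in the
Chapman–Enskog expansion (the printed second-order source we started from
is typographically corrupted; the implemented form reproduces
Hagen–Poiseuille to 0.02 % and Womersley flow at Wo = 11.2 to 1.4 %, with
second-order grid convergence — all asserted by tests).  The radial rows
sit at r_j = (j+½)Δx, so the axis is a specular-reflection plane with no
node at r = 0.  Rigid lattice-aligned surfaces (domain rim, FL caps,
endograft ring, outflow contraction, inlet/outlet collars, the closed
aortic valve plane) use halfway bounce-back; open ends impose equilibrium
populations at the target pressure with neighbor-extrapolated velocity.

**Walls.** Aortic wall and septum are one-dimensional curves X(s,t)
obeying the dynamic stretching+bending equation with simple supports (the
zero-curvature end condition is the natural boundary condition of the
Hermite-cubic discretization; the pinned positions are enforced exactly).
Stretching is geometrically nonlinear (2-point Gauss quadrature, Newton
iteration); bending and consistent mass are standard Hermite operators.
Time integration is implicit Newmark-β — (¼, ½) in standalone use, where
the suite verifies energy conservation, and the dissipative pair
(0.3025, 0.6) inside the coupled loop (trapezoidal Newmark leaves stiff
modes marginally stable, and the partitioned exchange pumps them).

Two constitutive choices go beyond the flap equation.  (i) The **outer
wall** carries the hoop restoring force Eh·(Y−Y₀)/R₀² of an intact
axisymmetric vessel: without circumferential stiffness an axisymmetric
membrane inflates unboundedly under mean pressure.  With Eh = 530 Pa·m the
classical Moens–Korteweg speed √(Eh/2ρr) is 5 m/s.  (ii) The **septum** is
hoop-free — the dissection destroys the flap's circumferential integrity,
which is also why it can move millimetres — but carries 5 % pretension: a
slack membrane has zero compressive stiffness and crumples at marker
wavelength under load.

**Inlet.** Time-varying-compliance LV.  C_v(t) = 1/E(t) with the
double-Hill normalized elastance (m₁ = 1.32, m₂ = 27.4, τ₁ = 0.269√T,
τ₂ = 0.452√T, peak-normalized), E(t) = E_min + (E_es − E_min)·e_n(t), so
min C_v = 1/E_es exactly.  The characteristic times scale with √T, giving
the systole a larger fraction of shorter cycles.  The diastolic floor
E_min = 0.08 mmHg/ml is held fixed when contractility is varied (passive
stiffness is not altered by inotropy).  Filling: while the passive pressure
is below the constant atrial pressure p_fill, the ventricle rests at
p_v = p_fill on its passive compliance, which fixes the end-diastolic
volume.  Ejection integrates the pressure ODE with explicit RK2 at the
lattice step.  The valve opens when p_v exceeds the interface pressure by
1 mmHg (hysteresis margin) after a 0.1 T closed interval, and closes when
the inflow reaches zero after a 2 % T open interval; the margins prevent
open/close chatter at the crossing, which otherwise destabilizes the run.
p_fill is the single calibration constant, set once (11.2 mmHg) against the
5.7 L/min baseline cardiac-output anchor; the partitioned scheme loses
robustness above p_fill ≈ 11.5, which caps the delivered CO at ≈ 5.4 L/min
(within the anchor's ±10 % band).

**Outlet.** Extension tube: a 10 cm elastic segment whose stretching
stiffness is back-computed by a static inflation test so its volume
compliance equals the tabulated 3.14×10⁻¹¹ m³/Pa, then a rigid contraction
to κ = 0.4 of the radius ending at constant pressure (60 mmHg).  The
contraction region carries a viscosity sponge (τ = 0.51) whose Poiseuille
drop supplies a peripheral resistance of ≈ 0.35 mmHg·s/ml and regularizes
the exit jet.

**Perivascular side and distributed outflow.** The annulus outside the
outer wall ends in a constant-pressure tissue reservoir at 10 mmHg, so the
wall works against a fixed external pressure and keeps its hoop
compliance.  The immersed wall is measurably permeable at this resolution
(≈ 0.4 ml s⁻¹ mmHg⁻¹ per cm of vessel with the double marker row); rather
than fight this numerically we treat the permeation as the distributed
outflow of the branch vessels that the idealized geometry excludes.  The
reservoir pressure is kept well below diastolic pressure because an
axisymmetric wall cannot reproduce the three-dimensional buckling of a
real vessel at zero transmural pressure; the consequence is that mean
pressures in the distal half of the model run below clinical values.  The
summary indices are ratio- or flow-based and are insensitive to the
absolute level; pulse pressures are physiological (≈ 25–50 mmHg).

## Coupling scheme

The immersed-boundary module provides the implicit velocity-correction
contract: markers ordered once by rest axial position give a banded
A = I∘S (interpolation ∘ spreading, adjoint in the cylindrical inner
product with the ds·R/r metric); A·δV = V_wall − I(v*) is solved exactly by
a compiled banded LU; the correction force f = 2ρδv/Δt enters the Guo
channel, and the reaction −2ρδV/Δt per unit wall area returns to the
structure.  Solid lattice nodes are excluded consistently from
interpolation, spreading and A (momentum deposited on bounce-back nodes is
discarded by the collision, and keeping it in A makes markers near rigid
masks overcorrect).  Markers are collocated with the FEM nodes at 2Δx
spacing: every positional degree of freedom is directly observed, so no
structural mode can hide from the correction by aliasing, and the square
system stays far from singular (condition number ~60; at the 0.5Δx spacing
sometimes quoted for spreading-only schemes, neighboring markers are
indistinguishable on the lattice and A is numerically singular).

The naive sequential exchange (correct against Vⁿ, hand F_L to the wall,
step the wall) is an explicit partitioned coupling and is unconditionally
unstable for walls this light (fluid reaction per step ≈ 2ρ_f Δx/λ(A)
exceeds the wall inertia; observed growth ×6 per step).  The production
scheme therefore transmits the fluid load implicitly: the wall solve
carries an interface drag −c·(V^{n+1} − I(v*)) with per-marker
c = 2ρ_f(Δx/Δt)/rowsum(A), which for smooth fields equals the exact
immersed-boundary reaction; the lagged difference between the exact
reaction and the diagonal drag is added as an explicit force after
binomial smoothing along the wall (its marker-alternating content is
precisely what an explicit application would pump) and a two-point average
in time (suppressing the temporal Nyquist mode of the one-step lag).  The
velocity correction is then applied against the already-updated wall
velocities, so no-slip at the markers holds to 10⁻⁸ every step (tracked as
a run diagnostic and asserted in tests).  A second Gauss–Seidel pass of
the exchange is available (`coupling_passes`); it changes the summary
statistics by less than their scaled-down tolerances and is off by default
for runtime.

Stabilization around this core, each with its reason:

* **Virtual added mass** (20 ρ_f Δx, lumped on positions and as strip
  rotary inertia on slopes): stands in for the fluid inertia the one-step
  exchange cannot transmit; wall response at heart-rate harmonics is
  stiffness/pressure dominated, so the bias there is a few percent.
* **Ghost-moment relaxation at rate 1.2–1.4** on production nodes: the BGK
  non-hydrodynamic eigenvalue 1−1/τ → −1 as τ → ½ and the repeated IB
  forcing pumps those modes; partial relaxation damps them while keeping
  the sub-grid structure that makes the interface impermeable (full
  projection, i.e. rate 1, combined with enhanced bulk viscosity was
  measured to raise wall permeation by two orders of magnitude).
* **Enhanced bulk viscosity** (trace of the non-equilibrium stress at
  τ_bulk = 0.6) on production nodes: damps grid-scale acoustics excited at
  corners and valve events within a few steps; heart-rate wavelengths
  (thousands of cells) are untouched.  Plain BGK is kept on benchmark
  lattices, where halfway bounce-back exactness matters.
* **Structural damping**: stiffness-proportional (a_K = 5×10⁻³ s,
  including the hoop operator) for junction modes, plus a velocity-
  Laplacian "wall viscosity" (2×10⁵ N·s/m³) that is zero for rigid or
  long-wave motion and damps marker-scale flap flutter, whose restoring
  force is fluid (not structural) stiffness and therefore out of reach of
  stiffness-proportional damping.
* **Contact handling**: the septum may not approach the outer wall closer
  than 1.8Δx (septum + wall thickness plus one resolved fluid node) nor
  the axis closer than 1.5Δx, enforced by quadratic (C¹) one-sided
  penalties with near-critical damping and reaction on the facing wall;
  transiently coincident markers are deactivated for the step; the flap
  margins within 1 cm of each tear are clamped (the re-attachment line)
  and its two hinge elements are locally stiffened; a 1 m/s wall-velocity
  limiter and an admissible-band position projection act as last-resort
  backstops (inactive in normal operation).
* **Sponges**: entrance columns (τ ramp to 0.53 over 2 cm) damp corner
  acoustics from valve events; the contraction sponge doubles as the
  peripheral resistance (above).

## Discretization and run control (desk scale)

D/Δx = 16 (Δx = 1.25 mm), 20 000 steps per cycle (Δt = 50 µs at 60 bpm;
peak lattice velocity ≈ 0.09, τ = 0.50048 at Wo = 11.2), walls at 2Δx
node/marker spacing, zone waveforms sampled 500× per cycle with per-step
boxcar accumulation (max/min statistics such as pulse pressure would
otherwise alias sub-millisecond contact transients).

**Measurement window.** Per-cycle diagnostics over 9-cycle runs show that
the false-lumen dynamics do not converge to a one-beat periodic state: at
λ = 0.40 the per-cycle FL-averaged RFI settles into a clean two-beat
(period-doubled) limit cycle (alternating ≈ 85 / ≈ 48 from cycle 2
onward), and at λ = 0.13 it fluctuates ± 10 about ≈ 46 without locking.
A statistic of the final cycle alone is therefore parity-dependent. All
summary statistics are computed over the **final two cycles**. Per-beat-
defined indices — RFI and pulse pressure — are computed per cycle and
averaged over the window: the per-beat mean is the faithful statistic of
an index defined over one cardiac cycle, whereas a single integral over
the window would weight each beat by its transported volume and discount
the near-stagnant high-reversal beats of the alternans (and a max − min
of pressure across both beats would mix extremes of different beats).
Powers and cardiac output, which are genuinely integral quantities,
integrate over the whole window. Runs are fixed-length: 4 cycles for the baseline and endograft
conditions, 3 for the contractility and heart-rate conditions (cardiac
output is cycle-stable from cycle 2; the cycle-to-cycle zone-1 pressure
residual is still recorded). A 4-cycle run takes ≈ 3 minutes on one CPU;
the five acceptance conditions together ≈ 13 minutes.  Everything is
deterministic: rerunning a configuration reproduces its outputs
bit-exactly.

## What the desk scale does and does not show

* The solver cores are quantitatively correct against closed forms
  (Poiseuille < 1 %, Womersley at Wo = 11.2 < 2 %, beam statics < 1 %,
  first mode < 2 %, adjointness and action–reaction to round-off).
* The coupled model reproduces the baseline cardiac output (calibration
  anchor), the near-equality of the covered-FL pulse pressures
  (RPP(4,5) ≈ 0.02, RPP(4,6) ≈ 0.03 against clinical-model values 0.044 /
  0.073), their ordering RPP(4,5) < RPP(4,6) < RPP(4,7), the monotone
  growth of FL flow reversal with endograft length (RFI 48.9 → 54.7 →
  77.8 for λ = 0.13/0.40/0.66), the rise of LV pulsatile power with
  coverage, and the favourable effect of lower heart rate on flow
  reversal.
* Several quantities are known to be resolution-limited: the 3–4-cell FL
  annulus over-attenuates the pulse and flow transmitted into the covered
  FL (the discrete viscous resistance of a 2–4-cell gap exceeds its
  continuum value several-fold).  This overestimates the distal pulse
  amplification RPP(4,7), and it distorts the *shape* of the RFI-vs-λ
  curve: the short-graft FL is already over-shielded (RFI starts near
  49 % instead of low), so the steep-then-flat pattern of the original
  (a ≈ 65 % relative jump from short to medium, ≈ 12 % from medium to
  long) appears inverted at desk scale (≈ 12 % then ≈ 42 %), even though
  monotonicity survives.  These require roughly the original cluster
  resolution (D/Δx ≥ 32) to quantify.
* The contractility sweep reproduces the direction but not the magnitude
  of the cardiac-output drop: a once-calibrated elastance ventricle with a
  fixed diastolic floor and fixed filling pressure has
  dSV/dE_es ≈ p_es/E_es² (softened by afterload feedback), i.e. ≈ 1.5 % CO
  change for the 2.5 % E_es steps, an order of magnitude below the
  clinical-model slope.  Matching that slope would require recalibrating
  the preload per contractile state, which the single-anchor calibration
  deliberately avoids.

The model is axisymmetric with a single proximal and distal tear, a
Newtonian fluid, a perfectly rigid endograft and no aortic arch, branch
vessels, septal fenestrations or patient-specific geometry.
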