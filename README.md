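# dissectfsi

A coupled heart–aorta fluid–structure interaction model of Stanford type B
aortic dissection after thoracic endovascular repair (TEVAR), built to study
how the length of the implanted endograft, the heart rate and the left
ventricle's contractile state shape two clinically meaningful quantities:

* **false-lumen flow reversal** (the reverse flow index, a predictor of the
  false-lumen thrombosis that TEVAR aims to induce), and
* **left-ventricular pulsatile workload** (the price the heart pays for the
  stiff prosthesis).

## Who this is for

Cardiovascular-biomechanics researchers who want a desk-scale, fully
scriptable model of dissection hemodynamics — idealized enough to vary one
parameter at a time (endograft coverage λ, HR, E<sub>es</sub>), complete
enough to produce pressure/flow waveforms, wall and septal motion, and the
clinical summary indices.

## The model

An idealized axisymmetric aorta (radius r<sub>aorta</sub> = 1 cm, length
40 cm) contains a concentric true lumen (TL) and an annular false lumen (FL)
separated by a flexible intimal septum over a 29 cm dissected segment; the
lumina communicate through 1 cm tears at the two ends of the septum.  A
rigid endograft of length λ·L<sub>septum</sub> (λ ∈ 0.13…0.66) covers the
proximal tear.  Numerically:

* **Fluid** — incompressible axisymmetric D2Q9 lattice-Boltzmann (BGK with
  Guo forcing); curvature terms of the cylindrical Navier–Stokes equations
  enter as first-order mass sources and equivalent body forces.  The
  relaxation time follows from the physical viscosity so the baseline
  matches the clinical comparison condition, Womersley number
  Wo = r√(αρ/μ) = 11.2.
* **Walls** — the aortic wall and septum obey the dynamic
  stretching+bending equation
  ρ<sub>s</sub>h ∂²X/∂t² = ∂/∂s[Eh(1−|∂X/∂s|⁻¹)∂X/∂s] − ∂²/∂s²(EI ∂²X/∂s²) + F<sub>L</sub>
  with simple supports, discretized by Hermite-cubic finite elements and
  integrated by implicit Newmark-β with Newton iteration.  The outer wall
  additionally carries the hoop term Eh·w/R² of an intact axisymmetric
  vessel; the septum is hoop-free (a flap) with 5 % pretension.
* **Coupling** — implicit velocity-correction immersed boundary: marker
  corrections solve A·δV = V<sub>wall</sub> − I(v*) with a 4-point Peskin
  cosine kernel, spreading and interpolation adjoint in the cylindrical
  inner product, and the reaction returned to the walls.
* **Inlet** — a time-varying-compliance left ventricle,
  ∂p<sub>v</sub>/∂t = −(1/C<sub>v</sub>)[Ċ<sub>v</sub>p<sub>v</sub> + Q(0,t)],
  with a double-Hill elastance shape (min C<sub>v</sub> = 1/E<sub>es</sub>),
  valve opening on p<sub>v</sub> > p(0,t) and closure at zero inflow.
* **Outlet** — the extension-tube boundary model: an elastic segment whose
  stiffness is back-computed from the tabulated volume compliance, then a
  rigid contraction (κ = 0.4) ending at constant pressure.

Post-processing computes, per zone (1 TL root, 2–3 TL tears, 4–7 FL
proximal→distal): pulsatile power P̄<sub>pulse</sub> = P̄<sub>total</sub> −
p̄·q̄, the reverse flow index RFI = |∫Q<sub>rev</sub>|/(|∫Q<sub>rev</sub>| +
|∫Q<sub>fwd</sub>|)·100, relative pulse pressures RPP(i,j) =
|pp<sub>i</sub>−pp<sub>j</sub>|/pp<sub>j</sub>, and cardiac output.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```bash
python examples/run_baseline.py
```

runs the baseline (λ = 0.66, Wo = 11.2, HR 60, E<sub>es</sub> 2.05) and
prints, after the per-cycle progress lines:

```
cardiac output        : 5.38 L/min (mean aortic-root inflow over the final two cycles)
LV pulsatile power    : 748 mW (oscillatory part of the hydraulic power at zone 1)
FL-averaged RFI       : 77.8 % (retrograde fraction of false-lumen flow, zones 4-6)
RPP(4, 5)            : 0.022 (relative pulse pressure between FL zones)
RPP(4, 6)            : 0.030 (relative pulse pressure between FL zones)
RPP(4, 7)            : 6.937 (relative pulse pressure between FL zones)
converged             : True (cycle-to-cycle zone-1 pressure residual below tolerance)
```

All summary statistics are taken over the final two cardiac cycles (the
false-lumen dynamics need not settle into a one-beat periodic state; see
the measurement-window discussion in `docs/methods.md`).

A long endograft seals the proximal tear and shields the covered false
lumen, so its flow is mostly oscillatory slosh (high RFI — the
thrombosis-favourable state) and the covered-FL pulse pressures sit far
below the free distal segment (small RPP(4,5)/(4,6), large RPP(4,7); the
distal amplification is exaggerated at desk resolution — see the methods
note).  `examples/endograft_length_sweep.py` shows the λ trade-off and
`examples/validate_solvers.py` prints the analytic-benchmark errors.

The same machinery is scriptable from a shell:

```bash
dissectfsi run --out run_out
dissectfsi sweep --lambdas 0.13,0.40,0.66
dissectfsi benchmark --case womersley
```

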