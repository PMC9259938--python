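"""Run configuration: physical, geometric and numerical parameters.

All defaults correspond to the baseline idealized dissection model: a 40 cm
axisymmetric aorta (radius 1 cm) with a 29 cm dissected segment, a rigid
endograft covering a fraction ``lambda_ratio`` of the septum length, a
time-varying-elastance LV at the inlet and an extension-tube outflow model
(15 cm, contraction ratio 0.4).  A configuration is fully serializable to
YAML and a run is reproducible from its echoed config alone.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

from dissectfsi import units


@dataclass
class GeometryParams:
    """Idealized dissection geometry (lengths in cm)."""

    L_aorta: float = 40.0          #: length of the aortic model
    L_septum: float = 29.0         #: dissected segment length (incl. tears)
    r_aorta: float = 1.0           #: outer aortic radius
    r_TL: float = 0.5              #: true-lumen (septum) radius; the false
    #: lumen is typically the larger channel in type B dissection
    septum_start: float = 5.0      #: axial start of the dissected segment
    tear_width: float = 1.0        #: axial width of each tear opening
    lambda_ratio: float = 0.66     #: endograft length / septum length
    L_boundary: float = 15.0       #: outflow extension total length
    L_elastic_out: float = 10.0    #: elastic portion of the extension
    L_taper_out: float = 2.0       #: axial length of the rigid contraction taper
    kappa: float = 0.4             #: contraction ratio (radius after / before)
    rim_margin_nodes: int = 6      #: lattice nodes between outer wall and rigid rim


@dataclass
class FluidParams:
    """Blood properties (Newtonian)."""

    rho: float = 1060.0            #: density, kg/m^3
    mu: float = 3.5e-3             #: dynamic viscosity, Pa*s

    @property
    def nu_cm2s(self) -> float:
        """Kinematic viscosity in cm^2/s."""
        return self.mu / self.rho * 1.0e4


@dataclass
class WallParams:
    """Elastic wall and septum constitutive parameters.

    The bending coefficient EI is the one tabulated material constant; the
    stretching stiffness Eh of the aortic wall is set so that the classical
    Moens-Korteweg pulse-wave speed sqrt(Eh/(2 rho r)) is about 5 m/s, and
    the septum uses the same elastic modulus at half the thickness.
    """

    EI: float = 2.0e-7             #: bending stiffness, Pa*m^3 (aortic wall)
    EI_septum: float = 2.0e-7      #: bending stiffness, Pa*m^3 (septum)
    Eh_aorta: float = 530.0        #: stretching stiffness, Pa*m
    Eh_septum: float = 265.0       #: stretching stiffness, Pa*m
    h_aorta: float = 2.0e-3        #: wall thickness, m
    h_septum: float = 1.0e-3       #: septum thickness, m
    rho_s: float = 1100.0          #: wall density, kg/m^3
    flutter_damping: float = 2.0e5  #: wall viscosity (Kelvin-Voigt velocity-
    #: Laplacian damping), N s/m^3: zero for rigid or long-wavelength
    #: motion, full strength for marker-scale flap flutter, whose restoring
    #: force is fluid (not structural) stiffness and therefore out of reach
    #: of stiffness-proportional damping
    stiffness_damping: float = 5.0e-3  #: stiffness-proportional (Rayleigh)
    #: damping coefficient a_K, seconds: C = a_K K.  Damping ratio a_K*w/2
    #: is ~0.016 at 1 Hz and ~0.6 at 40 Hz: modest at heart-rate
    #: harmonics, strong for the short-wavelength junction modes that the
    #: partitioned fluid exchange can otherwise pump.
    added_mass_coeff: float = 20.0  #: virtual fluid mass per unit area, in
    #: units of rho_fluid*dx, lumped into the wall mass matrix in coupled
    #: runs.  It represents the physical fluid inertia carried along with
    #: the wall (order rho_f * r) that the one-step interface exchange does
    #: not transmit; it also regularizes marker-scale wall modes.  Wall
    #: response at heart-rate harmonics is stiffness/pressure dominated, so
    #: the extra inertia shifts it by only a few percent.  Set 0 for
    #: standalone structural use.


@dataclass
class InletParams:
    """Time-varying-elastance left ventricle.

    ``Ees`` scales the systolic (active) elastance; the passive diastolic
    elastance floor ``Emin`` is held fixed when contractility is varied.
    ``p_fill`` is the constant atrial filling pressure: it is the single
    calibration constant of the inlet model, chosen once so that the coupled
    baseline (HR 60 bpm, Ees 2.05 mmHg/ml) delivers 5.7 L/min cardiac output.
    """

    HR: float = 60.0               #: heart rate, bpm
    Ees: float = 2.05              #: end-systolic elastance, mmHg/ml
    Emin: float = 0.08             #: diastolic elastance floor, mmHg/ml
    Vdead: float = 4.0             #: dead volume, ml
    p_fill: float = 11.2           #: filling pressure, mmHg (calibration anchor)
    # double-Hill normalized elastance shape (systolic fraction scales with HR)
    m1: float = 1.32
    m2: float = 27.4
    tau1_frac: float = 0.269       #: tau1 / T at 60 bpm
    tau2_frac: float = 0.452       #: tau2 / T at 60 bpm

    @property
    def period(self) -> float:
        """Cardiac period T in seconds."""
        return 60.0 / self.HR


@dataclass
class OutflowParams:
    """Extension-tube outflow boundary model."""

    C_outflow: float = 3.14e-11    #: volume compliance of the elastic segment, m^3/Pa
    p_out: float = 60.0            #: constant pressure at the open end, mmHg
    p_tissue: float = 10.0         #: perivascular reservoir pressure, mmHg.
    #: The immersed outer wall is permeable at desk scale; its Darcy-like
    #: conductance together with this reservoir forms a distributed outflow
    #: standing in for the branch vessels excluded from the idealized
    #: geometry.  The low reservoir pressure keeps the transmural pressure
    #: positive everywhere (an axisymmetric wall cannot buckle the way a
    #: real vessel does at zero transmural pressure).
    tau_sponge: float = 0.51       #: relaxation time in the contraction sponge
    #: zone.  The elevated viscosity regularizes the contraction jet and its
    #: Poiseuille drop supplies the peripheral resistance of the truncated
    #: bed; together with p_out it sets mean aortic pressure ~90-95 mmHg at
    #: 5.7 L/min cardiac output.


@dataclass
class NumericsParams:
    """Discretization and run control."""

    nodes_per_diameter: int = 32   #: D/dx
    steps_per_cycle: int = 50000   #: T/dt
    cycles: int = 10               #: maximum cardiac cycles
    min_cycles: int = 3            #: cycles before convergence may stop the run
    conv_tol: float = 0.005        #: cycle-to-cycle relative L2 of zone-1 pressure
    marker_spacing: float = 2.0    #: IB marker spacing in lattice units; must
    #: exceed 1 so the square velocity-correction system stays invertible
    #: (sub-grid marker spacing makes neighboring markers indistinguishable
    #: on the lattice and the interpolation-spreading matrix numerically
    #: singular)
    samples_per_cycle: int = 500   #: zone-waveform sampling cadence
    newton_tol: float = 1.0e-10    #: wall FEM Newton tolerance (relative)
    coupling_passes: int = 1       #: Gauss-Seidel passes of the wall/
    #: velocity-correction exchange per time step (the implicit interface
    #: drag already carries the dominant coupling; a second pass changes
    #: the summary statistics by less than their scaled-down tolerance)
    seed: int = 0                  #: unused by the deterministic physics


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    wall: WallParams = field(default_factory=WallParams)
    inlet: InletParams = field(default_factory=InletParams)
    outflow: OutflowParams = field(default_factory=OutflowParams)
    numerics: NumericsParams = field(default_factory=NumericsParams)

    # ----- derived lattice scales -------------------------------------------------
    @property
    def dx_cm(self) -> float:
        return 2.0 * self.geometry.r_aorta / self.numerics.nodes_per_diameter

    @property
    def dt_s(self) -> float:
        return self.inlet.period / self.numerics.steps_per_cycle

    @property
    def velocity_scale(self) -> float:
        """Physical velocity (cm/s) of one lattice velocity unit."""
        return self.dx_cm / self.dt_s

    @property
    def pressure_scale_pa(self) -> float:
        """Physical pressure (Pa) of one lattice pressure unit (cs^2*drho)."""
        u = self.velocity_scale * units.CM_TO_M
        return self.fluid.rho * u * u

    @property
    def nu_lattice(self) -> float:
        return self.fluid.nu_cm2s * self.dt_s / self.dx_cm**2

    @property
    def tau(self) -> float:
        """BGK relaxation time implied by the physical viscosity."""
        return 0.5 + 3.0 * self.nu_lattice

    @property
    def womersley(self) -> float:
        alpha = 2.0 * math.pi / self.inlet.period
        return womersley_from_physical(
            self.geometry.r_aorta, alpha, self.fluid.rho, self.fluid.mu
        )

    def validate(self) -> None:
        if not (0.0 < self.geometry.lambda_ratio <= 1.0):
            raise ValueError(f"lambda_ratio must be in (0, 1], got {self.geometry.lambda_ratio}")
        if not (0.0 < self.geometry.r_TL < self.geometry.r_aorta):
            raise ValueError("require 0 < r_TL < r_aorta")
        if not (0.0 < self.geometry.kappa < 1.0):
            raise ValueError(f"kappa must be in (0, 1), got {self.geometry.kappa}")
        if self.numerics.nodes_per_diameter < 16:
            raise ValueError("nodes_per_diameter must be >= 16")
        tau = self.tau
        if not (0.5 < tau <= 1.5):
            raise ValueError(f"relaxation time tau={tau:.4f} outside (0.5, 1.5]")

    # ----- serialization ----------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            geometry=GeometryParams(**d.get("geometry", {})),
            fluid=FluidParams(**d.get("fluid", {})),
            wall=WallParams(**d.get("wall", {})),
            inlet=InletParams(**d.get("inlet", {})),
            outflow=OutflowParams(**d.get("outflow", {})),
            numerics=NumericsParams(**d.get("numerics", {})),
        )

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "RunConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, ValueError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d or {})


def womersley_from_physical(r_cm: float, alpha: float, rho: float, mu: float) -> float:
    """Wo = r*sqrt(alpha*rho/mu), r in cm, alpha in rad/s, SI fluid properties."""
    if min(r_cm, alpha, rho, mu) <= 0.0:
        raise ValueError("Womersley number requires positive arguments")
    return r_cm * units.CM_TO_M * math.sqrt(alpha * rho / mu)


def desk_scale_config(**overrides) -> RunConfig:
    """Baseline configuration at desk-scale resolution.

    Resolution D/dx = 16 with 20 000 steps per cycle and 5 cardiac cycles:
    the problem size used for the reduced-scale reproduction runs on a single
    CPU.  The blood viscosity is set so that the baseline matches the
    clinical comparison condition Wo = 11.2 at 60 bpm (the printed blood
    properties and the stated Womersley number cannot hold simultaneously;
    the Womersley number is the dynamically relevant condition).  Keyword
    overrides are applied to the nested dataclasses by dotted name, e.g.
    ``desk_scale_config(**{"geometry.lambda_ratio": 0.40})``.
    """
    cfg = RunConfig()
    cfg.fluid.mu = 5.31e-3   # -> Wo = 11.2 at HR 60, r = 1 cm
    cfg.numerics.nodes_per_diameter = 16
    cfg.numerics.steps_per_cycle = 20000
    cfg.numerics.cycles = 4
    cfg.numerics.min_cycles = 4
    for key, value in overrides.items():
        section, _, name = key.partition(".")
        if not name:
            raise KeyError(f"override {key!r} must be 'section.field'")
        sub = getattr(cfg, section)
        if not hasattr(sub, name):
            raise KeyError(f"unknown config field {key!r}")
        setattr(sub, name, value)
    return cfg
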