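"""Inlet and outlet boundary models.

Inlet: the left ventricle as a time-varying compliance Cv(t) (the inverse
of the time-varying elastance).  LV pressure and volume obey
Vv - Vdead = Cv(t) pv; during ejection the pressure follows the ODE

    dpv/dt = -(1/Cv) [ dCv/dt * pv + Q(0, t) ]

with the aortic boundary pressure set to pv.  The aortic valve closes when
the inflow reaches zero and reopens when pv exceeds the interface pressure.
Diastolic filling is modeled with a constant atrial filling pressure
p_fill: while the passive LV pressure is below p_fill the ventricle fills
along its passive compliance (pv = p_fill), which fixes the end-diastolic
volume; the systolic elastance scale Ees is varied independently of the
passive (diastolic) elastance floor.

The elastance waveform uses the standard double-Hill normalized shape with
a systolic duration that scales with sqrt(T), so the systolic fraction of
the cycle grows with heart rate.

Outlet: the extension-tube model appends an elastic segment (whose
stretching stiffness is back-computed so its static volume compliance
equals C_outflow) and a rigid contraction with radius ratio kappa ending in
an open constant-pressure outlet; the contraction supplies the peripheral
resistance, the elastic segment the truncated vasculature's compliance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from dissectfsi import units
from dissectfsi.config import InletParams, OutflowParams, WallParams
from dissectfsi.wall import make_straight_wall


# ----------------------------------------------------------------------------
# Elastance waveform
# ----------------------------------------------------------------------------
def _double_hill_shape(phase, m1, m2, tau1, tau2):
    g1 = (phase / tau1) ** m1
    g2 = (phase / tau2) ** m2
    return (g1 / (1.0 + g1)) / (1.0 + g2)


def normalized_elastance(t, T, m1=1.32, m2=27.4, tau1_frac=0.269, tau2_frac=0.452):
    """Double-Hill normalized elastance e_n(t) in [0, 1], period T.

    The characteristic times scale as sqrt(T) relative to a 1 s reference
    cycle, so systole occupies a larger fraction of short cycles.
    """
    t = np.asarray(t, dtype=float) % T
    tau1 = tau1_frac * math.sqrt(T)
    tau2 = tau2_frac * math.sqrt(T)
    shape = _double_hill_shape(t, m1, m2, tau1, tau2)
    # normalize the peak over the cycle
    tt = np.linspace(0.0, T, 2001)
    peak = _double_hill_shape(tt, m1, m2, tau1, tau2).max()
    return shape / peak


def elastance_waveform(t, HR, Ees, Emin=0.08, **shape_kw):
    """LV compliance Cv(t) = 1/E(t), ml/mmHg.

    E(t) = Emin + (Ees - Emin) e_n(t): the minimum compliance over the cycle
    is exactly 1/Ees (end-systole), the diastolic plateau is 1/Emin.
    """
    if Ees <= 0.0:
        raise ValueError("Ees must be positive")
    T = 60.0 / HR
    en = normalized_elastance(t, T, **shape_kw)
    return 1.0 / (Emin + (Ees - Emin) * en)


class ElastanceInlet:
    """Stateful LV inlet: pressure, volume and valve phase.

    Works in clinical units (mmHg, ml, s); the simulation driver does the
    lattice conversions.
    """

    REFRACTORY_FRAC = 0.02  # min open time before Q <= 0 may close the valve
    CLOSED_FRAC = 0.1       # min closed time before the valve may reopen
    REOPEN_MARGIN = 1.0     # reopening hysteresis, mmHg (avoids chatter)

    def __init__(self, params: InletParams):
        self.p = params
        self.T = params.period
        if params.Ees <= 0 or params.Emin <= 0 or params.Ees <= params.Emin:
            raise ValueError("need Ees > Emin > 0")
        # dense elastance table for fast periodic lookup + derivative
        self._nt = 4096
        tt = np.arange(self._nt) * (self.T / self._nt)
        self._Cv = elastance_waveform(
            tt, params.HR, params.Ees, params.Emin,
            m1=params.m1, m2=params.m2,
            tau1_frac=params.tau1_frac, tau2_frac=params.tau2_frac,
        )
        self.valve_open = False
        self._t_open = -1.0
        self._t_close = -1.0e9
        self.pv = params.p_fill
        self.Vv = params.Vdead + self.Cv(0.0) * params.p_fill

    def Cv(self, t):
        x = (t % self.T) / self.T * self._nt
        i0 = int(x) % self._nt
        i1 = (i0 + 1) % self._nt
        w = x - int(x)
        return (1.0 - w) * self._Cv[i0] + w * self._Cv[i1]

    def dCv_dt(self, t):
        eps = self.T / self._nt
        return (self.Cv(t + eps) - self.Cv(t - eps)) / (2.0 * eps)

    def step(self, t, dt, Q_inlet, p_interface):
        """Advance the LV state over [t, t+dt].

        Q_inlet: aortic root flow in ml/s (positive into the aorta) during
        the step; p_interface: fluid pressure at x = 0, mmHg.  Returns the
        pressure imposed at the inlet if the valve is open, else None.
        """
        Cv = self.Cv(t)
        if Cv <= 0.0:
            raise RuntimeError("non-positive LV compliance")
        if self.valve_open:
            # explicit RK2 on dpv/dt = -(dCv/dt pv + Q)/Cv
            def rhs(tt, pv):
                return -(self.dCv_dt(tt) * pv + Q_inlet) / self.Cv(tt)

            k1 = rhs(t, self.pv)
            k2 = rhs(t + dt, self.pv + dt * k1)
            self.pv += 0.5 * dt * (k1 + k2)
            self.Vv -= Q_inlet * dt
            if Q_inlet <= 0.0 and (t - self._t_open) > self.REFRACTORY_FRAC * self.T:
                self.valve_open = False
                self._t_close = t
            return self.pv if self.valve_open else None
        # valve closed: passive pressure from the stored volume
        pv_passive = (self.Vv - self.p.Vdead) / Cv
        if pv_passive <= self.p.p_fill:
            # diastolic filling at constant atrial pressure
            self.pv = self.p.p_fill
            self.Vv = self.p.Vdead + Cv * self.p.p_fill
        else:
            # isovolumic contraction / relaxation
            self.pv = pv_passive
            if (self.pv > p_interface + self.REOPEN_MARGIN
                    and (t - self._t_close) > self.CLOSED_FRAC * self.T):
                self.valve_open = True
                self._t_open = t
                return self.pv
        return None


# ----------------------------------------------------------------------------
# Extension-tube outflow
# ----------------------------------------------------------------------------
@dataclass
class ExtensionTubeOutflow:
    """Built outflow extension: elastic segment stiffness and contraction."""

    L_boundary: float          #: cm
    L_elastic: float           #: cm
    kappa: float
    C_outflow: float           #: m^3/Pa
    Eh_elastic: float          #: Pa m, back-computed from C_outflow
    r_contraction: float       #: cm
    p_out: float               #: mmHg


def segment_compliance(
    Eh, L_cm, r_cm, EI, mass_per_area, p_mid_mmhg=100.0, dp_mmhg=10.0, n_el=64
):
    """Static volume compliance dV/dp (m^3/Pa) of a pinned elastic segment.

    The segment is inflated quasi-statically (load continuation) to
    p_mid -/+ dp and the secant slope of the enclosed volume
    V = int 2 pi r w dx is returned.
    """
    L = L_cm * units.CM_TO_M
    r0 = r_cm * units.CM_TO_M
    vols = []
    for p_mmhg in (p_mid_mmhg - dp_mmhg, p_mid_mmhg + dp_mmhg):
        wall = make_straight_wall(0.0, L, r0, L / n_el, Eh, EI, mass_per_area)
        p_target = p_mmhg * units.MMHG_TO_PA
        nm = wall.n_markers
        for frac in np.linspace(0.15, 1.0, 8):
            F = np.zeros((nm, 2))
            F[:, 1] = frac * p_target
            wall.static_solve(wall.nodal_forces_from_markers(F))
        pos = wall.positions()
        w = pos[:, 1] - r0
        x = pos[:, 0]
        vols.append(np.trapezoid(2.0 * np.pi * pos[:, 1] * w, x))
    dp = 2.0 * dp_mmhg * units.MMHG_TO_PA
    return (vols[1] - vols[0]) / dp


def calibrate_extension_stiffness(
    C_target, L_cm, r_cm, EI, mass_per_area, bracket=(1e2, 1e11)
):
    """Back-compute the elastic-segment Eh whose static volume compliance
    matches C_target (m^3/Pa)."""

    def f(logEh):
        c = segment_compliance(10.0 ** logEh, L_cm, r_cm, EI, mass_per_area)
        return math.log10(c) - math.log10(C_target)

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    logEh = brentq(f, lo, hi, xtol=1e-3)
    return 10.0 ** logEh


def build_outflow(geometry, outflow: OutflowParams, wall: WallParams):
    """Construct the outflow extension model for a built geometry."""
    if not (0.0 < geometry.kappa < 1.0):
        raise ValueError("contraction ratio kappa must be in (0, 1)")
    Eh = calibrate_extension_stiffness(
        outflow.C_outflow,
        geometry.L_elastic_out,
        geometry.r_aorta,
        wall.EI,
        wall.rho_s * wall.h_aorta,
    )
    return ExtensionTubeOutflow(
        L_boundary=geometry.L_boundary,
        L_elastic=geometry.L_elastic_out,
        kappa=geometry.kappa,
        C_outflow=outflow.C_outflow,
        Eh_elastic=Eh,
        r_contraction=geometry.kappa * geometry.r_aorta,
        p_out=outflow.p_out,
    )
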