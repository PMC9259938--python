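"""Incompressible axisymmetric single-relaxation-time D2Q9 lattice-Boltzmann
solver.

The model evolves distribution functions f_i on a pseudo-Cartesian (x, r)
grid; pressure is carried by rho0 (p = cs^2 rho0) while momentum uses the
constant reference density (= 1 in lattice units).  Curvature terms of the
cylindrical Navier-Stokes equations are recovered by first- and
second-order source terms added at collision; the radial rows sit at
r_j = j + 1/2 so the axis (a specular symmetry plane) carries no node.

The module-level functions are straightforward array implementations of the
individual operations (useful for testing and as documentation); the
:class:`Lattice` class drives the compiled kernels.
"""

from __future__ import annotations

import warnings

import numpy as np

from dissectfsi import _kernels as K

EX = K.EX.astype(np.float64)
ER = K.ER.astype(np.float64)
W = K.W
CS2 = K.CS2


def equilibrium(rho0, vx, vr):
    """Equilibrium distributions of the incompressible D2Q9 model.

    f_i^eq = w_i rho0 + w_i [3 e.v + 4.5 (e.v)^2 - 1.5 v^2]  (cs^2 = 1/3).
    """
    rho0 = np.asarray(rho0, dtype=float)
    vx = np.asarray(vx, dtype=float)
    vr = np.asarray(vr, dtype=float)
    speed = np.sqrt(vx * vx + vr * vr)
    if np.any(speed >= 0.1):
        warnings.warn(
            f"lattice velocity {speed.max():.3f} >= 0.1 c; compressibility "
            "errors grow quadratically with Mach number",
            RuntimeWarning,
            stacklevel=2,
        )
    shape = (9,) + np.broadcast(rho0, vx).shape
    feq = np.empty(shape)
    usq = vx * vx + vr * vr
    for k in range(9):
        eu = EX[k] * vx + ER[k] * vr
        feq[k] = W[k] * (rho0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
    return feq


def forcing_term(vx, vr, fEx, fEr, tau):
    """Guo forcing F_i = (1 - 1/(2 tau)) w_i [ (e-v)/cs^2 + (e.v)/cs^4 e ] . f."""
    pref = 1.0 - 0.5 / tau
    shape = (9,) + np.broadcast(np.asarray(vx), np.asarray(fEx)).shape
    F = np.empty(shape)
    for k in range(9):
        eu = EX[k] * vx + ER[k] * vr
        F[k] = pref * W[k] * (
            3.0 * ((EX[k] - vx) * fEx + (ER[k] - vr) * fEr)
            + 9.0 * eu * (EX[k] * fEx + ER[k] * fEr)
        )
    return F


def axisymmetric_source(vx, vr, r, tau, dvxdr=0.0, dvrdr=0.0):
    """Axisymmetric curvature corrections (dt = 1).

    Returns ``(H, Fx, Fr)``: the first-order mass source per direction,
    H_i = -w_i vr / r, which restores the cylindrical continuity term, and
    the equivalent body force carrying the curvature terms of the momentum
    equations,

        Fx = nu dvx/dr / r - vx vr / r,
        Fr = nu (dvr/dr / r - vr / r^2) - vr^2 / r,

    applied through the second-order Guo forcing channel.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("axisymmetric source requires r > 0 at all nodes")
    nu = (tau - 0.5) / 3.0
    h1 = -vr / r
    shape = (9,) + np.broadcast(np.asarray(vx), r).shape
    H = np.empty(shape)
    for k in range(9):
        H[k] = W[k] * h1
    Fx = nu * dvxdr / r - vx * vr / r
    Fr = nu * (dvrdr / r - vr / r**2) - vr * vr / r
    return H, Fx, Fr


def velocity_gradients(f, feq, tau, vr):
    """Strain components from non-equilibrium moments plus a finite difference.

    Returns (dvx/dr + dvr/dx, dvx/dx, dvr/dr, dvr/dx): the first three from
    rho nu (d_b v_a + d_a v_b) = -(1 - 1/(2 tau)) sum_i fneq e_ia e_ib, the
    last from a central difference of vr along x (one-sided at the edges).
    """
    nu = (tau - 0.5) / 3.0
    fneq = f - feq
    pixx = np.einsum("k...,k,k->...", fneq, EX, EX)
    pixr = np.einsum("k...,k,k->...", fneq, EX, ER)
    pirr = np.einsum("k...,k,k->...", fneq, ER, ER)
    coef = -(1.0 - 0.5 / tau)
    dvxdx = coef * pixx / (2.0 * nu)
    sum_xr = coef * pixr / nu
    dvrdr = coef * pirr / (2.0 * nu)
    vr = np.asarray(vr, dtype=float)
    dvrdx = np.gradient(vr, axis=0) if vr.ndim else np.zeros(())
    return sum_xr, dvxdx, dvrdr, dvrdx


class Lattice:
    """D2Q9 lattice with solid-mask bounce-back walls and optional open ends.

    Parameters
    ----------
    nx, nr
        Grid size; row j sits at r = j + 1/2 lattice units.
    tau
        Relaxation time (scalar or per-node field); kinematic viscosity is
        nu = (tau - 1/2)/3.
    solid
        Boolean mask of rigid nodes (halfway bounce-back).
    axisym
        Apply the axisymmetric source terms (False gives a planar channel).
    periodic_x
        Periodic in x (used by the analytic benchmarks).
    """

    def __init__(self, nx, nr, tau, solid=None, axisym=True, periodic_x=False):
        self.nx, self.nr = int(nx), int(nr)
        self.tau_field = np.full((nx, nr), float(tau)) if np.isscalar(tau) else np.array(tau, dtype=float)
        self.solid = np.zeros((nx, nr), dtype=np.bool_) if solid is None else solid.astype(np.bool_)
        self.axisym = bool(axisym)
        self.periodic_x = bool(periodic_x)
        self.f = np.empty((9, nx, nr))
        self._fc = np.empty_like(self.f)
        self.rho0 = np.ones((nx, nr))
        self.vx = np.zeros((nx, nr))
        self.vr = np.zeros((nx, nr))
        self.r = np.broadcast_to(np.arange(nr) + 0.5, (nx, nr))
        self.inlet_open = False
        self.outlet_open = False
        self.rho_in = 1.0
        self.rho_out = 1.0
        #: regularized-collision mask (set near immersed boundaries)
        self.reg_mask = np.zeros((nx, nr), dtype=np.bool_)
        #: enhanced-bulk-viscosity mask (set away from immersed boundaries)
        self.bulk_mask = np.zeros((nx, nr), dtype=np.bool_)
        #: mild near-interface bulk relaxation time (0 = physical rate)
        self.tau_bulk_near = 0.0
        #: constant-pressure tissue reservoir row (None = disabled)
        self.tissue_row = -1
        self.rho_tissue = 1.0
        self.initialize()

    @property
    def fluid(self):
        return ~self.solid

    def initialize(self, rho0=None, vx=None, vr=None):
        if rho0 is not None:
            self.rho0[:] = rho0
        if vx is not None:
            self.vx[:] = vx
        if vr is not None:
            self.vr[:] = vr
        usq = np.sqrt(self.vx**2 + self.vr**2)
        for k in range(9):
            eu = EX[k] * self.vx + ER[k] * self.vr
            self.f[k] = W[k] * (self.rho0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq**2)

    def update_macro(self):
        """rho0 = sum f; momentum (pre-force) = sum e f."""
        K.macro_fields(self.f, self.solid, self.rho0, self.vx, self.vr)

    def collide_stream(self, fEx=None, fEr=None):
        """One collision + streaming pass using the current macro fields.

        The caller is responsible for the macro update (and for adding the
        half-force velocity shift: v = sum e f + fE/2) before calling.
        """
        z = np.zeros((self.nx, self.nr))
        fEx = z if fEx is None else fEx
        fEr = z if fEr is None else fEr
        K.collide(
            self.f, self._fc, self.rho0, self.vx, self.vr,
            fEx, fEr, self.tau_field, self.solid, self.axisym, self.reg_mask,
            self.bulk_mask, self.tau_bulk_near,
        )
        K.stream(
            self._fc, self.f, self.solid,
            self.inlet_open, self.outlet_open, self.periodic_x,
        )
        if self.inlet_open:
            K.pressure_inlet(self.f, self.solid, self.rho_in)
        if self.outlet_open:
            K.pressure_outlet(self.f, self.solid, self.rho_out)
        if self.tissue_row >= 0:
            K.tissue_reservoir_row(self.f, self.solid, self.tissue_row, self.rho_tissue)

    def step(self, fEx=None, fEr=None):
        """Macro update + collide/stream (simple body-force driven runs)."""
        self.update_macro()
        if fEx is not None:
            self.vx += 0.5 * np.where(self.fluid, fEx, 0.0)
        if fEr is not None:
            self.vr += 0.5 * np.where(self.fluid, fEr, 0.0)
        self.collide_stream(fEx, fEr)
        if not np.all(np.isfinite(self.f)):
            vmax = np.nanmax(np.abs(self.vx)) if np.isfinite(self.vx).any() else np.nan
            raise FloatingPointError(
                f"lattice diverged (NaN/overflow); last max |vx| = {vmax:.3g}"
            )

    def mass(self):
        """Total mass sum_nodes sum_i f_i over fluid nodes."""
        return float(self.f.sum(axis=0)[self.fluid].sum())
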