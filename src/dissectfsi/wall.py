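"""Dynamic large-deflection model of the elastic aortic wall and intimal
septum.

Each wall is a one-dimensional curve X(s, t) = (X, Y) in the (x, r) plane
governed by (per unit area, SI units)

    rho_s h X_tt = d/ds [ Eh (1 - |X_s|^-1) X_s ] - d2/ds2 (EI X_ss) + F_L

with simple supports at both ends: X = X0 and zero curvature.  The bending
operator uses Hermite-cubic elements (C1 continuity), the geometrically
nonlinear stretching term is integrated with 2-point Gauss quadrature on
the same elements, and time integration is implicit Newmark-beta
(beta = 1/4, gamma = 1/2) with Newton iteration on the stretching term.
The zero-curvature end condition is the natural boundary condition of the
Hermite discretization; the pinned-position condition is enforced exactly.

Markers for the immersed-boundary coupling are either collocated with the
FEM nodes (coupled use: every positional degree of freedom is directly
observed by a marker) or placed at two points per element (standalone
consistent-load tests); their kinematics come from Hermite interpolation
and their tractions are distributed back as consistent nodal loads.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

from dissectfsi import _kernels as K

BW = 7  # half-bandwidth of the 4-DOF-per-node Hermite discretization


def _banded_to_dense(Ab, bw):
    n = Ab.shape[1]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(max(0, i - bw), min(n, i + bw + 1)):
            A[i, j] = Ab[bw + i - j, j]
    return A


class WallModel:
    """One elastic wall curve with its discrete operators and state.

    Parameters
    ----------
    X0 : (n, 2) array
        Rest node positions in meters (monotone arclength; uniform spacing).
    Eh, EI : float or (n-1,) array
        Stretching (Pa m) and bending (Pa m^3) stiffness per element.
    mass_per_area : float or (n-1,) array
        rho_s * thickness (kg/m^2), plus any virtual added mass.
    """

    def __init__(self, X0, Eh, EI, mass_per_area, newton_tol=1e-10, max_iter=8,
                 marker_spacing=None, virtual_mass_per_area=0.0,
                 markers_at_nodes=False, stiffness_damping=0.0,
                 viscosity_damping=0.0, hoop_stiffness=0.0,
                 prestretch=0.0):
        X0 = np.asarray(X0, dtype=float)
        if X0.ndim != 2 or X0.shape[1] != 2 or X0.shape[0] < 5:
            raise ValueError("X0 must be (n, 2) with n >= 5 (>= 4 elements)")
        self.n_nodes = X0.shape[0]
        seg = np.diff(X0, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        if not np.allclose(lens, lens[0], rtol=1e-8):
            raise ValueError("nodes must be uniformly spaced along the rest curve")
        self.h = float(lens[0])
        n_el = self.n_nodes - 1
        self.Eh_e = np.broadcast_to(np.asarray(Eh, dtype=float), (n_el,)).copy()
        self.EI_e = np.broadcast_to(np.asarray(EI, dtype=float), (n_el,)).copy()
        self.mass_e = np.broadcast_to(np.asarray(mass_per_area, dtype=float), (n_el,)).copy()
        if np.any(self.EI_e < 0) or np.any(self.Eh_e < 0) or np.any(self.mass_e <= 0):
            raise ValueError("stiffness must be >= 0 and mass > 0")
        if np.all(self.EI_e == 0) and np.all(self.Eh_e == 0):
            raise ValueError("wall needs nonzero stiffness")

        ndof = 4 * self.n_nodes
        self.ndof = ndof
        self.q = np.zeros(ndof)
        tang = np.vstack([seg / lens[:, None], seg[-1:] / lens[-1]])
        tang_node = np.vstack([tang[:1], 0.5 * (tang[:-1] + tang[1:])[: self.n_nodes - 2], tang[-1:]])
        tang_node /= np.hypot(tang_node[:, 0], tang_node[:, 1])[:, None]
        self.q[0::4] = X0[:, 0]
        self.q[1::4] = tang_node[:, 0]
        self.q[2::4] = X0[:, 1]
        self.q[3::4] = tang_node[:, 1]
        self.q0 = self.q.copy()
        self.v = np.zeros(ndof)
        self.a = np.zeros(ndof)

        self.Kb = np.zeros((2 * BW + 1, ndof))
        self.M = np.zeros((2 * BW + 1, ndof))
        K.fem_constant_matrices(self.n_nodes, self.h, self.EI_e, self.mass_e, BW, self.Kb, self.M)
        # Virtual added mass for partitioned FSI stability: the coupled
        # solve advances the wall with M + Mv.  The extra inertia stands in
        # for the fluid mass the immersed-boundary reaction couples to the
        # wall within one time step and must exceed 2 rho_f dx / lambda_min
        # of the interpolation-spreading matrix; wall motion at heart-rate
        # harmonics is stiffness/pressure dominated, so the added inertia
        # perturbs the response there by only a few percent.
        # The virtual mass is lumped (diagonal): a consistent mass matrix
        # underweights node-alternating modes by nearly an order of
        # magnitude, which would defeat the stabilization exactly for the
        # marker-scale modes that need it most.
        self.virtual_mass = float(virtual_mass_per_area)
        if self.virtual_mass > 0.0:
            self.Mtot = self.M.copy()
            h_node = np.full(self.n_nodes, self.h)
            h_node[0] = h_node[-1] = 0.5 * self.h
            mv = self.virtual_mass * h_node
            # translational inertia on the value DOFs, rotary inertia
            # (strip moment h^2/12) on the slope DOFs: both channels of the
            # Hermite discretization receive marker forces and need it
            for comp in (0, 2):
                self.Mtot[BW, comp::4] += mv
            for comp in (1, 3):
                self.Mtot[BW, comp::4] += mv * self.h**2 / 12.0
        else:
            self.Mtot = self.M

        self.fixed = np.zeros(ndof, dtype=np.bool_)
        for node in (0, self.n_nodes - 1):
            self.fixed[4 * node] = True      # X position pinned
            self.fixed[4 * node + 2] = True  # Y position pinned
        self.newton_tol = float(newton_tol)
        self.max_iter = int(max_iter)
        self.n_frozen_steps = 0
        self._zero = np.zeros(ndof)
        # one-sided radial barrier (unset by default): an implicit stiff
        # penalty Y <= bar_hi that stands in for the finite wall/septum
        # thickness when two surfaces would otherwise pinch together
        self.bar_hi = np.full(ndof, 1.0e30)
        self.bar_lo = np.full(ndof, -1.0e30)
        self.bar_k = np.zeros(ndof)
        self.bar_c = np.zeros(ndof)
        # hoop (circumferential) stiffness for an intact axisymmetric
        # vessel: radial restoring force Eh (Y - Y0) / R0^2 per unit area,
        # lumped on the radial value DOFs (0 for a plane-strain strip or a
        # dissected flap whose circumferential integrity is lost)
        self.hoop = np.zeros(ndof)
        hs = np.broadcast_to(np.asarray(hoop_stiffness, dtype=float), (self.n_nodes,))
        h_node = np.full(self.n_nodes, self.h)
        h_node[0] = h_node[-1] = 0.5 * self.h
        self.hoop[2::4] = hs * h_node
        # structural damping operator: stiffness-proportional part
        # aK (Kb + Kt0 + hoop) plus a velocity-Laplacian "wall viscosity"
        # (Kelvin-Voigt): the Laplacian term is zero for rigid/long-wave
        # motion and damps marker-scale flutter (restored by fluid, not
        # structural, stiffness) at full strength
        self.pre = 1.0 + float(prestretch)
        aK = float(stiffness_damping)
        Kd = self.Kb.copy()
        R0 = np.zeros(ndof)
        K.fem_stretch_residual_jacobian(self.q0, self.h, self.Eh_e, BW, R0, Kd, self.pre)
        Kd[BW, :] += self.hoop
        self.Cd = aK * Kd
        cL = float(viscosity_damping)
        if cL > 0.0:
            w_lap = 0.5 * cL * self.h
            for comp in (0, 2):
                dofs = np.arange(comp, ndof, 4)
                self.Cd[BW, dofs[1:-1]] += 2.0 * w_lap
                self.Cd[BW, dofs[0]] += w_lap
                self.Cd[BW, dofs[-1]] += w_lap
                # off-diagonal neighbor coupling (distance 4 in DOF index)
                self.Cd[BW - 4, dofs[1:]] += -w_lap
                self.Cd[BW + 4, dofs[:-1]] += -w_lap

        # immersed-boundary marker points along the curve.  The coupled
        # simulation collocates markers at the FEM nodes (markers_at_nodes):
        # every positional DOF is then directly observed by a marker, so no
        # structural mode can hide from the no-slip correction by aliasing
        # (a node-alternating zigzag evaluated at element midpoints is
        # invisible, and an unobserved mode receiving distributed forces is
        # pumped without damping).  Standalone use defaults to two markers
        # per element (spacing h/2) for smooth consistent loads.
        L = self.h * n_el
        if markers_at_nodes:
            n_m = self.n_nodes
            self.elem_m = np.minimum(np.arange(n_m, dtype=np.int64), n_el - 1)
            self.xi_m = np.where(np.arange(n_m) < n_el, 0.0, 1.0)
            self.ds_m = np.full(n_m, self.h)
            self.ds_m[0] = self.ds_m[-1] = 0.5 * self.h
        else:
            spacing = 0.5 * self.h if marker_spacing is None else float(marker_spacing)
            n_m = max(4, int(round(L / spacing)))
            ds0 = L / n_m
            s_m = (np.arange(n_m) + 0.5) * ds0
            self.elem_m = np.minimum((s_m / self.h).astype(np.int64), n_el - 1)
            self.xi_m = s_m / self.h - self.elem_m
            self.ds_m = np.full(n_m, ds0)
        self.n_markers = n_m

    def set_radial_barrier(self, y_max, y_min=None, engagement=3.0e-4):
        """Cap the radial coordinate of all nodes at y_max (meters, scalar
        or per node) with a quadratic one-sided penalty whose force reaches
        the physiologic pressure scale (~5 kPa) at the given engagement
        depth (m)."""
        h_node = np.full(self.n_nodes, self.h)
        h_node[0] = h_node[-1] = 0.5 * self.h
        k2 = 5.0e3 / engagement**2        # N/m^4 quadratic coefficient
        self.bar_hi[2::4] = y_max
        if y_min is not None:
            self.bar_lo[2::4] = y_min
        self.bar_k[2::4] = k2 * h_node
        # contact damping, scaled with engagement depth inside the kernel
        m_eff = float(np.mean(self.mass_e)) + self.virtual_mass
        self.bar_c[2::4] = 2.0 * np.sqrt(k2 * m_eff) * h_node

    def barrier_forces(self):
        """Current one-sided penalty force per node (radial, N/m^2);
        the equal-opposite reaction for the facing surface."""
        y = self.q[2::4]
        delta = np.maximum(y - self.bar_hi[2::4], 0.0)
        h_node = np.full(self.n_nodes, self.h)
        h_node[0] = h_node[-1] = 0.5 * self.h
        return (self.bar_k[2::4] / h_node) * delta * delta

    def pin_nodes(self, node_indices):
        """Clamp the positions of extra nodes (rigid collars at junctions
        with lattice-aligned boundaries)."""
        for n in np.atleast_1d(node_indices):
            self.fixed[4 * int(n)] = True
            self.fixed[4 * int(n) + 2] = True

    # ----- kinematics -------------------------------------------------------------
    def marker_states(self, v_extrapolation=0.0):
        """Marker positions (m), velocities (m/s) and arclength weights (m).

        ``v_extrapolation`` dt' evaluates velocities at v + dt' a (used by
        the coupled driver as a half-step predictor)."""
        Xm = np.empty((self.n_markers, 2))
        Vm = np.empty((self.n_markers, 3))
        v = self.v if v_extrapolation == 0.0 else self.v + v_extrapolation * self.a
        K.hermite_eval_markers(self.q, v, self.h, self.xi_m, self.elem_m, Xm, Vm)
        ds = self.ds_m * Vm[:, 2]  # local stretch scales the weight
        return Xm, Vm[:, :2], ds

    def nodal_forces_from_markers(self, F_markers):
        """Consistent nodal load vector from per-marker tractions (Pa)."""
        F_markers = np.asarray(F_markers, dtype=float)
        Fn = np.empty(self.ndof)
        K.hermite_distribute_forces(F_markers, self.h, self.xi_m, self.elem_m,
                                    self.ds_m, Fn)
        return Fn

    # ----- dynamics ---------------------------------------------------------------
    def init_acceleration(self, Fext=None):
        """Consistent initial acceleration M a = Fext - Fint(q)."""
        Fext = np.zeros(self.ndof) if Fext is None else Fext
        R = np.empty(self.ndof)
        K.banded_matvec(self.Kb, BW, self.q, R)
        J = np.zeros_like(self.Kb)
        K.fem_stretch_residual_jacobian(self.q, self.h, self.Eh_e, BW, R, J, self.pre)
        rhs = Fext - R
        Mf = self.M.copy()
        for d in np.where(self.fixed)[0]:
            lo, hi = max(0, d - BW), min(self.ndof, d + BW + 1)
            for c in range(lo, hi):
                Mf[BW + d - c, c] = 0.0
                Mf[BW + c - d, d] = 0.0
            Mf[BW, d] = 1.0
            rhs[d] = 0.0
        K.banded_lu(Mf, BW)
        K.banded_solve(Mf, BW, rhs)
        self.a[:] = rhs

    def step(self, Fext, dt, beta=0.25, gamma=0.5, drag_c=None, drag_target=None):
        """Advance one implicit Newmark step; raises on Newton failure after
        an internal time-step halving retry.

        ``drag_c`` (per marker, N s/m^3) and ``drag_target`` (per marker,
        (n, 2) m/s) add the implicit interface drag
        -drag_c (V^{n+1} - target) used by the coupled FSI driver; they
        require node-collocated markers."""
        cdrag = self._zero
        vtarget = self._zero
        if drag_c is not None:
            cdrag = np.zeros(self.ndof)
            vtarget = np.zeros(self.ndof)
            cd = drag_c * self.ds_m
            cdrag[0::4] = cd
            cdrag[2::4] = cd
            vtarget[0::4] = drag_target[:, 0]
            vtarget[2::4] = drag_target[:, 1]
        saved = (self.q.copy(), self.v.copy(), self.a.copy())
        its = K.fem_newmark_step(
            self.q, self.v, self.a, Fext, self.h, self.Eh_e, self.Kb, self.Mtot,
            BW, self.fixed, dt, beta, gamma, self.newton_tol, self.max_iter,
            cdrag, vtarget, self.Cd, self.hoop, self.q0,
            self.bar_hi, self.bar_lo, self.bar_k, self.bar_c, self.pre,
        )
        if its < 0:
            # restore the pre-step state and retry with two half steps
            self.q[:], self.v[:], self.a[:] = saved
            for _ in range(2):
                its = K.fem_newmark_step(
                    self.q, self.v, self.a, Fext, self.h, self.Eh_e, self.Kb,
                    self.Mtot, BW, self.fixed, 0.5 * dt, beta, gamma,
                    self.newton_tol, self.max_iter, cdrag, vtarget,
                    self.Cd, self.hoop, self.q0,
                    self.bar_hi, self.bar_lo, self.bar_k, self.bar_c, self.pre,
                )
            if its < 0:
                # last resort: freeze the wall for this step (restore the
                # pre-step state with halved velocities); logged via the
                # freeze counter so a run that needs this often is suspect
                self.q[:], self.v[:], self.a[:] = saved
                self.v *= 0.5
                self.a[:] = 0.0
                self.n_frozen_steps += 1
        return its

    def static_solve(self, Fext):
        """Static equilibrium under a nodal load vector (Newton)."""
        its = K.fem_static_solve(
            self.q, Fext, self.h, self.Eh_e, self.Kb, BW, self.fixed,
            self.newton_tol, 200, self.hoop, self.q0, self.pre,
        )
        if its < 0:
            raise RuntimeError("static Newton solve did not converge")
        return self.q

    # ----- diagnostics ------------------------------------------------------------
    def positions(self):
        return np.column_stack([self.q[0::4], self.q[2::4]])

    def velocities(self):
        return np.column_stack([self.v[0::4], self.v[2::4]])

    def energy(self):
        """Kinetic + bending + stretching energy (per unit width)."""
        tmp = np.empty(self.ndof)
        K.banded_matvec(self.M, BW, self.v, tmp)
        kin = 0.5 * float(self.v @ tmp)
        K.banded_matvec(self.Kb, BW, self.q, tmp)
        bend = 0.5 * float(self.q @ tmp)
        stretch = 0.0
        for e in range(self.n_nodes - 1):
            for xi in K.GAUSS_XI:
                N = np.empty(4)
                dN = np.empty(4)
                K._hermite(xi, self.h, N, dN)
                dofs_x = [4 * e, 4 * e + 1, 4 * e + 4, 4 * e + 5]
                dofs_y = [4 * e + 2, 4 * e + 3, 4 * e + 6, 4 * e + 7]
                gx = float(dN @ self.q[dofs_x])
                gy = float(dN @ self.q[dofs_y])
                stretch += 0.5 * self.h * 0.5 * self.Eh_e[e] * (np.hypot(gx, gy) - 1.0) ** 2
        return kin + bend + stretch

    def end_constraint_residual(self):
        """Max violation of the simple-support conditions (positions exact;
        curvature at the ends is the natural BC, reported for diagnostics)."""
        pos_err = 0.0
        for node in (0, self.n_nodes - 1):
            pos_err = max(
                pos_err,
                abs(self.q[4 * node] - self.q0[4 * node]),
                abs(self.q[4 * node + 2] - self.q0[4 * node + 2]),
            )
        return pos_err

    def modal_frequencies(self, n_modes=3):
        """Small-vibration angular frequencies about the rest state (rad/s)."""
        R = np.zeros(self.ndof)
        Kt = np.zeros_like(self.Kb)
        K.fem_stretch_residual_jacobian(self.q0, self.h, self.Eh_e, BW, R, Kt, self.pre)
        A = _banded_to_dense(self.Kb, BW) + _banded_to_dense(Kt, BW)
        M = _banded_to_dense(self.M, BW)
        free = ~self.fixed
        w2 = eigh(A[np.ix_(free, free)], M[np.ix_(free, free)], eigvals_only=True)
        w2 = np.sort(w2[w2 > 1e-12])
        return np.sqrt(w2[:n_modes])


def make_straight_wall(x_start, x_end, r, spacing, Eh, EI, mass_per_area, **kw):
    """Straight wall along x at constant radius r (SI meters)."""
    n = int(round((x_end - x_start) / spacing)) + 1
    x = np.linspace(x_start, x_end, n)
    X0 = np.column_stack([x, np.full(n, r)])
    return WallModel(X0, Eh, EI, mass_per_area, **kw)


def elasticity_sensitivity(make_run, E_scales, n_periods=1):
    """Radial displacement waveforms at the model center for a range of
    elasticity scale factors.

    ``make_run(scale)`` must return ``(t, y_center)`` for one cardiac cycle
    with all stiffnesses (Eh, EI) multiplied by ``scale``.  Returns a dict
    ``{scale: (t, y)}`` plus the matrix of pairwise correlation coefficients
    of the normalized waveforms (shape preservation metric).
    """
    out = {}
    for s in E_scales:
        t, y = make_run(s)
        out[s] = (np.asarray(t, dtype=float), np.asarray(y, dtype=float))
    scales = list(out)
    C = np.ones((len(scales), len(scales)))
    for i, a in enumerate(scales):
        for j, b in enumerate(scales):
            if j <= i:
                continue
            ya, yb = out[a][1], out[b][1]
            za = (ya - ya.mean()) / (ya.std() or 1.0)
            zb = (yb - yb.mean()) / (yb.std() or 1.0)
            C[i, j] = C[j, i] = float(np.mean(za * zb))
    return out, C
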