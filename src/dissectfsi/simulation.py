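"""Coupled LV-dissection simulation driver.

One time step advances the system in a fixed, documented order (see
:meth:`Simulation.fsi_step` for the full account of the interface-drag
coupling): macroscopic update; wall solve with implicit interface drag
toward the interpolated fluid velocity; exact no-slip velocity correction
against the updated wall velocities; LV elastance/valve update setting the
inlet condition; collision (Guo forcing + axisymmetric sources) and
streaming with the open-end pressure conditions.

Everything inside the loop is deterministic; rerunning a configuration
reproduces its outputs bit-exactly.
"""

from __future__ import annotations

import copy
import math
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from dissectfsi import units
from dissectfsi.boundary_models import ElastanceInlet, build_outflow
from dissectfsi.config import RunConfig
from dissectfsi.coupling import CouplingSystem
from dissectfsi.geometry import DissectionGeometry, build_dissection
from dissectfsi.hemodynamics import HemodynamicSummary, ZoneWaveform, summarize
from dissectfsi.lbm import Lattice
from dissectfsi.wall import WallModel, make_straight_wall


@dataclass
class RunArtifacts:
    """Raw per-sample traces of a run."""

    t: np.ndarray
    inlet: Dict[str, np.ndarray]
    zones: Dict[int, Dict[str, np.ndarray]]
    diagnostics: Dict[str, np.ndarray]
    septum_center: np.ndarray
    wall_center: np.ndarray
    cycle_residuals: List[float] = field(default_factory=list)


class Simulation:
    """Assembled coupled model for one configuration."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.geom: DissectionGeometry = build_dissection(config)
        g = self.geom
        num = config.numerics

        # --- scales -------------------------------------------------------
        self.dx_cm = config.dx_cm
        self.dx_m = self.dx_cm * units.CM_TO_M
        self.dt = config.dt_s
        self.Cu_cm = config.velocity_scale            # cm/s per lattice unit
        self.Cu_m = self.Cu_cm * units.CM_TO_M
        self.Cp = config.pressure_scale_pa            # Pa per lattice unit
        self.tau = config.tau

        # --- lattice ------------------------------------------------------
        self.j_wall = g.r_aorta / self.dx_cm          # wall radius, lattice
        self.nx = int(round(g.L_total / self.dx_cm)) + 1
        self.nr = int(round(self.j_wall)) + config.geometry.rim_margin_nodes + 1
        solid = np.zeros((self.nx, self.nr), dtype=bool)
        solid[:, self.nr - 1] = True                              # rigid rim
        rj = np.arange(self.nr) + 0.5
        # rigid collars: the outer wall coincides with the lattice plane
        # r = j_wall, so short segments at the inlet and at the junction
        # with the contraction are realized by halfway bounce-back instead
        # of immersed markers (no kernel clipping at the open ends)
        self.collar_cm = 2.0
        x_tmp = np.arange(self.nx) * self.dx_cm
        collar = (x_tmp <= self.collar_cm) | (x_tmp >= g.elastic_wall_span[1] - self.collar_cm)
        solid[np.ix_(collar, rj > self.j_wall)] = True
        # outflow contraction (rigid taper + narrow tube)
        x = np.arange(self.nx) * self.dx_cm
        xc = g.contraction_start
        r_out = g.r_contraction
        prof = np.where(
            x < xc, g.r_aorta,
            np.maximum(g.r_aorta - (g.r_aorta - r_out) * (x - xc) / g.L_taper_out, r_out),
        )
        mask = (x[:, None] >= xc) & (rj[None, :] > prof[:, None] / self.dx_cm)
        solid |= mask
        # false-lumen end caps at the two ends of the dissected segment.
        # The septum rest line is snapped to the nearest lattice face so
        # that the rigid endograft ring (one solid row outward of the line)
        # seals flush against it without narrowing the true lumen.
        r_sep = float(round(g.r_TL / self.dx_cm))
        self.r_sep_line = r_sep
        for xcap in (g.septum_span[0], g.septum_span[1]):
            icap = int(round(xcap / self.dx_cm))
            solid[icap, (rj > r_sep) & (rj < self.j_wall)] = True
        # viscosity sponge over the contraction (outflow regularization)
        tau_f = np.full((self.nx, self.nr), self.tau)
        ramp = np.clip((x - xc) / g.L_taper_out, 0.0, 1.0)
        tau_f += (config.outflow.tau_sponge - self.tau) * ramp[:, None]
        # short entrance sponge: damps corner acoustics excited by valve
        # events at the inlet plane (decays slowly at physical viscosity)
        ramp_in = np.clip(1.0 - x / self.collar_cm, 0.0, 1.0)
        tau_f += (0.53 - tau_f) * ramp_in[:, None]
        self.lat = Lattice(self.nx, self.nr, tau_f, solid=solid, axisym=True)
        self.lat.outlet_open = True
        self.lat.rho_out = 1.0
        # perivascular tissue reservoir: the row below the rigid rim holds
        # the tissue pressure, so the outer wall works against a constant
        # external pressure and keeps its hoop compliance
        self.lat.tissue_row = self.nr - 2

        # --- outflow + walls ---------------------------------------------
        self.outflow = build_outflow(g, config.outflow, config.wall)
        w = config.wall
        mv = w.added_mass_coeff * config.fluid.rho * self.dx_m
        # outer wall: aorta + elastic extension, between the rigid collars
        ds_wall = num.marker_spacing * self.dx_m   # wall nodes = IB markers
        x_w0 = self.collar_cm * units.CM_TO_M
        x_w1 = (g.elastic_wall_span[1] - self.collar_cm) * units.CM_TO_M
        n_el = int(round((x_w1 - x_w0) / ds_wall))
        Eh_e = np.where(
            x_w0 + (np.arange(n_el) + 0.5) * ds_wall < g.L_aorta * units.CM_TO_M,
            w.Eh_aorta, self.outflow.Eh_elastic,
        )
        self.wall_outer = WallModel(
            np.column_stack([
                np.linspace(x_w0, x_w1, n_el + 1),
                np.full(n_el + 1, g.r_aorta * units.CM_TO_M),
            ]),
            Eh_e, w.EI, w.rho_s * w.h_aorta,
            newton_tol=num.newton_tol,
            markers_at_nodes=True,
            virtual_mass_per_area=mv,
            stiffness_damping=w.stiffness_damping,
            viscosity_damping=w.flutter_damping,
            prestretch=0.02,
            hoop_stiffness=np.concatenate([Eh_e, Eh_e[-1:]])
            / (g.r_aorta * units.CM_TO_M) ** 2,
        )
        # flexible septum: from the endograft end to the distal tear
        xs0, xs1 = g.flexible_septum_span
        xs0 = round(xs0 / self.dx_cm) * self.dx_cm
        xs1 = round(xs1 / self.dx_cm) * self.dx_cm
        self.septum_span_flex = (xs0, xs1)
        n_el_s = int(round((xs1 - xs0) / self.dx_cm / num.marker_spacing))
        EI_s = np.full(n_el_s, w.EI_septum)
        # reinforced attachment edges: the flap's hinge regions are locally
        # stiffened so the elements next to the simple supports do not
        # flutter at marker scale under the tear jets
        EI_s[:2] *= 1.0e3
        EI_s[-2:] *= 1.0e3
        self.wall_septum = make_straight_wall(
            xs0 * units.CM_TO_M, xs1 * units.CM_TO_M, r_sep * self.dx_m,
            ds_wall, w.Eh_septum, EI_s, w.rho_s * w.h_septum,
            newton_tol=num.newton_tol,
            markers_at_nodes=True,
            virtual_mass_per_area=mv,
            stiffness_damping=w.stiffness_damping,
            viscosity_damping=w.flutter_damping,
            prestretch=0.05,
        )
        # tethered flap margins: the septum within 1 cm of each tear is
        # clamped (the re-attachment line of the dissection), which keeps
        # the thin free edge from folding through its support in the tear
        # jets
        n_pin = max(1, int(round(1.0 / (self.dx_cm * num.marker_spacing))))
        nn_s = self.wall_septum.n_nodes
        self.wall_septum.pin_nodes(list(range(n_pin + 1)) +
                                   list(range(nn_s - n_pin - 1, nn_s)))
        # finite-thickness barrier: the septum may not approach the outer
        # wall closer than ~1.8 lattice units (septum + wall thickness plus
        # one resolved fluid node); prevents geometric degeneracy of the
        # coupling system when the false lumen is squeezed shut in systole.
        # The cap follows the local outer-wall position (updated each step)
        # and its reaction is returned to the outer wall.
        self.gap_min_lat = 1.8
        self.wall_septum.set_radial_barrier(
            (self.j_wall - self.gap_min_lat) * self.dx_m,
            y_min=1.5 * self.dx_m,
        )
        self.walls = [self.wall_outer, self.wall_septum]

        # rigid endograft: a one-node-thick solid ring (halfway bounce-back
        # on both faces) at the lattice row containing the true-lumen
        # radius.  A solid ring seals the covered septum and the proximal
        # tear exactly; an immersed-marker graft would let the TL pulse
        # leak through into the covered false lumen.
        # ring row chosen so its outer face sits at (or just below) the
        # septum line: the flexible septum's pinned end stays in fluid
        j_graft = int(round(r_sep))      # ring occupies [r_sep, r_sep + 1]
        i_g0 = int(round(g.graft_span[0] / self.dx_cm))
        i_g1 = int(round(g.graft_span[1] / self.dx_cm))
        self.lat.solid[i_g0:i_g1 + 1, j_graft] = True
        solid[i_g0:i_g1 + 1, j_graft] = True
        self.graft_markers = np.zeros((0, 2))
        self.graft_ds = np.zeros(0)

        # global coupling system (markers ordered by rest x)
        Xr = self._marker_positions_lattice()
        self.coupling = CouplingSystem(self.nx, self.nr, Xr, solid=solid)
        # Regularized collision over the whole fluid: at tau ~ 0.5 the BGK
        # ghost modes are marginally damped and the immersed-boundary
        # forcing pumps them (a partially regularized domain reflects ghost
        # waves at the zone boundary).  The bounce-back surfaces of this
        # model are seals and sponge-zone walls, so their small
        # regularization-induced wall-offset change is immaterial.
        reg = np.ones((self.nx, self.nr), dtype=bool)
        reg[0, :] = False      # open-end planes keep plain BGK
        reg[-1, :] = False
        self.lat.reg_mask = reg
        # enhanced bulk viscosity only beyond kernel reach (3 cells) of any
        # marker rest line (dilated by the wall excursion allowance)
        bulk = np.ones((self.nx, self.nr), dtype=bool)
        bulk[0, :] = False
        bulk[-1, :] = False
        for xm, rm in Xr:
            i0 = max(0, int(xm) - 4)
            i1 = min(self.nx, int(xm) + 5)
            j0 = max(0, int(rm - 0.5) - 4)
            j1 = min(self.nr, int(rm - 0.5) + 5)
            bulk[i0:i1, j0:j1] = False
        self.lat.bulk_mask = bulk
        self.lat.tau_bulk_near = 0.6   # uniform enhanced bulk viscosity:
        # needed for systolic stability near the interfaces; the resulting
        # interface permeability is part of the distributed-Windkessel
        # outflow model (see OutflowParams.p_tissue)

        # --- inlet --------------------------------------------------------
        self.inlet = ElastanceInlet(config.inlet)
        self.T = config.inlet.period
        self.N = num.steps_per_cycle
        self.sample_every = max(1, self.N // num.samples_per_cycle)

        self.zone_i = {z.zone: int(round(z.x / self.dx_cm)) for z in g.zone_stations}
        self.rj = rj
        self.p_out = config.outflow.p_out

        self.fEx = np.zeros((self.nx, self.nr))
        self.fEr = np.zeros((self.nx, self.nr))
        self._F_extra = None
        self._F_prev = None
        self._Iv_prev = None
        self._sept_reaction = None
        # admissible radial bands for the position projection backstop
        self._y_bounds = [
            ((self.j_wall - 2.0) * self.dx_m, (self.nr - 3.0) * self.dx_m),
            (1.2 * self.dx_m, (self.j_wall - 1.2) * self.dx_m),
        ]
        self._acc_keys = (["Q_in", "p_if"] +
                          [f"z{z}_{suf}" for z in self.zone_i
                           for suf in ("pTL", "QTL", "pFL", "QFL", "QFLf", "QFLr")])
        self._reset_acc()
        jin = rj < self.j_wall
        self._inlet_area_lat = float(np.sum(2.0 * np.pi * rj[jin]))
        self._rho_closed = self.p_to_rho(self.p_out)
        self.t = 0.0
        self.step_count = 0
        self._init_fluid()

    # ------------------------------------------------------------------
    def _init_fluid(self, p_init_mmhg=None):
        # start at the outlet pressure: no initial transient through the
        # contraction; the LV charges the system over the first beats
        if p_init_mmhg is None:
            p_init_mmhg = self.p_out
        rho = self.p_to_rho(p_init_mmhg)
        self.lat.rho_tissue = self.p_to_rho(self.cfg.outflow.p_tissue)
        self.lat.initialize(rho0=np.full((self.nx, self.nr), rho))
        self.lat.update_macro()

    def p_to_rho(self, p_mmhg):
        return 1.0 + 3.0 * (p_mmhg - self.p_out) * units.MMHG_TO_PA / self.Cp

    def rho_to_p(self, rho):
        return (rho - 1.0) / 3.0 * self.Cp * units.PA_TO_MMHG + self.p_out

    # ------------------------------------------------------------------
    def _marker_positions_lattice(self):
        Xs = []
        for wll in self.walls:
            Xm, _, _ = wll.marker_states()
            Xs.append(Xm / self.dx_m)
        Xs.append(self.graft_markers)
        # slaved second layer of the outer wall (sealing row, +1 dx outward)
        Xo = Xs[0].copy()
        Xo[:, 1] += 1.0
        Xs.append(Xo)
        return np.vstack(Xs)

    def _marker_states_lattice(self):
        Xs, Vs, dss = [], [], []
        for wll in self.walls:
            Xm, Vm, ds = wll.marker_states()
            Xs.append(Xm / self.dx_m)
            Vs.append(Vm / self.Cu_m)
            dss.append(ds / self.dx_m)
        Xs.append(self.graft_markers)
        Vs.append(np.zeros_like(self.graft_markers))
        dss.append(self.graft_ds)
        # slaved sealing row: rides 1 dx outside the outer wall with the
        # same velocity, halving the immersed-interface permeability that
        # would otherwise drain the vessel toward the tissue reservoir
        Xo = Xs[0].copy()
        Xo[:, 1] += 1.0
        Xs.append(Xo)
        Vs.append(Vs[0])
        dss.append(dss[0])
        return np.vstack(Xs), np.vstack(Vs), np.concatenate(dss)

    # ------------------------------------------------------------------
    def _septum_radius_lattice(self, i):
        """Current septum lattice radius at lattice column i."""
        x = i * self.dx_cm
        if not (self.septum_span_flex[0] < x < self.septum_span_flex[1]):
            return self.r_sep_line
        Xm = self._septum_pos_cache
        return float(np.interp(x, Xm[:, 0], Xm[:, 1])) / self.dx_cm

    def inlet_flow(self):
        """Aortic root flow Q(0, t) in ml/s (positive into the aorta)."""
        j = self.rj < self.j_wall
        q_lat = float(np.sum(self.lat.vx[0, j] * 2.0 * np.pi * self.rj[j]))
        return q_lat * self.Cu_cm * self.dx_cm**2

    def interface_pressure(self):
        j = self.rj < self.j_wall
        return float(np.mean(self.rho_to_p(self.lat.rho0[0, j])))

    # ------------------------------------------------------------------
    def fsi_step(self):
        """One coupled time step.

        The fluid reaction reaches the elastic walls through an implicit
        interface drag -c (V^{n+1} - I(v)) inside the structural solve,
        with per-marker c matched to the row sums of the velocity-correction
        matrix so that for smooth fields the transmitted traction equals the
        exact immersed-boundary reaction; the previous step's difference
        between the exact reaction and the diagonal drag enters as a lagged
        explicit force, so the traction is asymptotically exact.  The
        wall-update / velocity-correction pair is Gauss-Seidel sub-iterated
        (walls restart from the step's initial state each pass, the second
        pass sees the once-corrected fluid), which removes the one-step
        phase lag of a purely sequential exchange; the final correction
        enforces no-slip exactly against the final wall velocities.
        """
        lat = self.lat
        lat.update_macro()
        # fluid velocity guard (see the wall limiter below)
        np.clip(lat.vx, -0.45, 0.45, out=lat.vx)
        np.clip(lat.vr, -0.45, 0.45, out=lat.vr)
        vx0 = lat.vx.copy()
        vr0 = lat.vr.copy()
        saved_walls = [(w.q.copy(), w.v.copy(), w.a.copy()) for w in self.walls]

        X, V, ds = self._marker_states_lattice()
        self.coupling.update_markers(X, ds)
        c_all = 2.0 * self.Cp / (self.coupling.row_sum * self.Cu_m)

        n_pass = self.cfg.numerics.coupling_passes
        for ip in range(n_pass):
            Ivx = self.coupling.marker_values(lat.vx)
            Ivr = self.coupling.marker_values(lat.vr)
            Iv = np.column_stack([Ivx, Ivr])
            if ip == 0:
                # half-sum with the previous step's target: suppresses the
                # temporal Nyquist mode of the exchange
                if self._Iv_prev is None:
                    self._Iv_prev = Iv
                Iv_f = 0.5 * (Iv + self._Iv_prev)
                self._Iv_prev = Iv
            else:
                Iv_f = Iv
                for w, st in zip(self.walls, saved_walls):
                    w.q[:], w.v[:], w.a[:] = st[0], st[1], st[2]
                lat.vx[:, :] = vx0
                lat.vr[:, :] = vr0

            # minimum-gap barrier: cap the septum under the local outer wall
            xs_nodes = self.wall_septum.q[0::4]
            Xo = self.wall_outer.positions()
            wall_r = np.interp(xs_nodes, Xo[:, 0], Xo[:, 1])
            self.wall_septum.bar_hi[2::4] = np.minimum(
                wall_r - self.gap_min_lat * self.dx_m,
                (self.j_wall - self.gap_min_lat) * self.dx_m,
            )

            off = 0
            for wll in self.walls:
                nm = wll.n_markers
                c_m = c_all[off:off + nm]
                target = Iv_f[off:off + nm] * self.Cu_m
                Fext = wll._zero
                if self._F_extra is not None:
                    Fext = wll.nodal_forces_from_markers(self._F_extra[off:off + nm])
                if wll is self.wall_outer and self._sept_reaction is not None:
                    Fr = np.zeros((nm, 2))
                    Fr[:, 1] = np.interp(
                        wll.q[0::4], self._sept_reaction[0], self._sept_reaction[1],
                        left=0.0, right=0.0,
                    )
                    Fext = Fext + wll.nodal_forces_from_markers(Fr)
                wll.step(Fext, self.dt, beta=0.3025, gamma=0.6,
                         drag_c=c_m, drag_target=target)
                # numerical safety limiters: wall velocities capped at 1 m/s
                # (several times the physiologic wall-speed scale) and
                # positions projected onto the admissible band; the soft
                # penalty barriers keep these inactive in normal operation
                np.clip(wll.v[0::4], -1.0, 1.0, out=wll.v[0::4])
                np.clip(wll.v[2::4], -1.0, 1.0, out=wll.v[2::4])
                np.clip(wll.v[1::4], -2.0e3, 2.0e3, out=wll.v[1::4])
                np.clip(wll.v[3::4], -2.0e3, 2.0e3, out=wll.v[3::4])
                y = wll.q[2::4]
                lo, hi = self._y_bounds[self.walls.index(wll)]
                clamped = (y < lo) | (y > hi)
                if clamped.any():
                    np.clip(y, lo, hi, out=y)
                    wll.v[2::4][clamped] = 0.0
                    wll.a[2::4][clamped] = 0.0
                xq = wll.q[0::4]
                x0 = wll.q0[0::4]
                xc = np.abs(xq - x0) > 1.5 * self.dx_m
                if xc.any():
                    np.clip(xq, x0 - 1.5 * self.dx_m, x0 + 1.5 * self.dx_m, out=xq)
                    wll.v[0::4][xc] = 0.0
                    wll.a[0::4][xc] = 0.0
                off += nm

            self._sept_reaction = (self.wall_septum.q[0::4].copy(),
                                   self.wall_septum.barrier_forces())

            # no-slip correction against the new wall velocities
            _, V2, _ = self._marker_states_lattice()
            F = self.coupling.correct(lat.vx, lat.vr, V2[:, 0], V2[:, 1],
                                      self.fEx, self.fEr)

        rhs = self.coupling.last_rhs
        F_new = F * self.Cp + c_all[:, None] * rhs * self.Cu_m
        # fold the slaved sealing row's reaction onto its base markers
        n_out = self.wall_outer.n_markers
        F_new[:n_out] += F_new[-n_out:]
        # spatial binomial smoothing per wall: the explicit correction only
        # carries the smooth-field difference between the exact reaction
        # and the diagonal drag; its marker-alternating content is exactly
        # the part the lagged explicit application would pump
        off = 0
        for wll in self.walls:
            nm = wll.n_markers
            seg = F_new[off:off + nm]
            if nm > 2:
                sm = seg.copy()
                sm[1:-1] = 0.25 * seg[:-2] + 0.5 * seg[1:-1] + 0.25 * seg[2:]
                F_new[off:off + nm] = sm
            off += nm
        if self._F_prev is None:
            self._F_prev = F_new
        self._F_extra = 0.5 * (F_new + self._F_prev)
        self._F_prev = F_new

        # inlet LV update: pressure condition p(0,t) = pv while the valve
        # is open, halfway bounce-back (Q = 0) while it is closed
        Q = self.inlet_flow()
        p_if = self.interface_pressure()
        p_in = self.inlet.step(self.t, self.dt, Q, p_if)
        if p_in is None:
            lat.inlet_open = False
        else:
            lat.inlet_open = True
            lat.rho_in = self.p_to_rho(p_in)

        lat.collide_stream(self.fEx, self.fEr)

        if self.step_count % 3 == 0:
            self._accumulate()
        self.t += self.dt
        self.step_count += 1

    # ------------------------------------------------------------------
    def _accumulate(self):
        """Per-step accumulation of zone quantities (boxcar anti-aliasing
        over the sampling interval; max-min statistics like pulse pressure
        would otherwise be corrupted by sub-millisecond contact/jet
        transients)."""
        lat = self.lat
        acc = self._acc
        Xm, _, _ = self.wall_septum.marker_states()
        self._septum_pos_cache = Xm * units.M_TO_CM
        g = self.geom
        lat_p = None
        for z, i in self.zone_i.items():
            rs = self._septum_radius_lattice(i)
            xz = i * self.dx_cm
            in_dis = g.septum_span[0] < xz < g.septum_span[1]
            jTL = self.rj < (rs if in_dis else self.j_wall)
            jTL &= ~lat.solid[i]
            vx = lat.vx[i]
            w2pi = 2.0 * np.pi * self.rj * self.Cu_cm * self.dx_cm**2
            pcol = self.rho_to_p(lat.rho0[i])
            acc[f"z{z}_pTL"] += float(np.mean(pcol[jTL])) if jTL.any() else np.nan
            acc[f"z{z}_QTL"] += float(np.sum(vx[jTL] * w2pi[jTL]))
            if in_dis:
                jFL = (self.rj > rs) & (self.rj < self.j_wall) & ~lat.solid[i]
                acc[f"z{z}_pFL"] += float(np.mean(pcol[jFL])) if jFL.any() else np.nan
                acc[f"z{z}_QFL"] += float(np.sum(vx[jFL] * w2pi[jFL]))
                acc[f"z{z}_QFLf"] += float(np.sum(np.maximum(vx[jFL], 0.0) * w2pi[jFL]))
                acc[f"z{z}_QFLr"] += float(np.sum(np.minimum(vx[jFL], 0.0) * w2pi[jFL]))
            else:
                for suf in ("pFL", "QFL", "QFLf", "QFLr"):
                    acc[f"z{z}_{suf}"] += np.nan
        acc["Q_in"] += self.inlet_flow()
        acc["p_if"] += self.interface_pressure()
        self._acc_n += 1

    def _reset_acc(self):
        self._acc = {k: 0.0 for k in self._acc_keys}
        self._acc_n = 0

    def _sample(self, rec):
        lat = self.lat
        n = max(1, self._acc_n)
        Xm, _, _ = self.wall_septum.marker_states()
        self._septum_pos_cache = Xm * units.M_TO_CM
        rec["t"].append(self.t)
        rec["pv"].append(self.inlet.pv)
        rec["Vv"].append(self.inlet.Vv)
        rec["valve"].append(1.0 if self.inlet.valve_open else 0.0)
        if self._acc_n == 0:
            rec["Q_in"].append(self.inlet_flow())
            rec["p_if"].append(self.interface_pressure())
            for z in self.zone_i:
                for suf in ("pTL", "QTL", "pFL", "QFL", "QFLf", "QFLr"):
                    rec[f"z{z}_{suf}"].append(np.nan)
        else:
            rec["Q_in"].append(self._acc["Q_in"] / n)
            rec["p_if"].append(self._acc["p_if"] / n)
            for z in self.zone_i:
                for suf in ("pTL", "QTL", "pFL", "QFL", "QFLf", "QFLr"):
                    rec[f"z{z}_{suf}"].append(self._acc[f"z{z}_{suf}"] / n)
        self._reset_acc()
        g = self.geom
        x_mid = 0.5 * (g.septum_span[0] + g.septum_span[1])
        rec["y_septum_mid"].append(
            float(np.interp(x_mid, self._septum_pos_cache[:, 0], self._septum_pos_cache[:, 1]))
        )
        Xo = self.wall_outer.positions() * units.M_TO_CM
        rec["y_wall_mid"].append(float(np.interp(x_mid, Xo[:, 0], Xo[:, 1])))
        rec["mass"].append(self.lat.mass())
        rec["max_v"].append(float(np.max(np.abs(lat.vx)) + np.max(np.abs(lat.vr))))
        rec["noslip"].append(self.coupling.last_residual)
        if not math.isfinite(rec["mass"][-1]):
            raise FloatingPointError(
                f"simulation diverged at t={self.t:.4f}s (step {self.step_count})"
            )

    # ------------------------------------------------------------------
    def run(self, progress=False):
        """Advance cycle by cycle until convergence (or the cycle budget)."""
        cfg = self.cfg
        rec: Dict[str, list] = {k: [] for k in ["t", "pv", "Vv", "valve", "Q_in", "p_if",
                                                "y_septum_mid", "y_wall_mid",
                                                "mass", "max_v", "noslip"]}
        for z in self.zone_i:
            for suf in ("pTL", "QTL", "pFL", "QFL", "QFLf", "QFLr"):
                rec[f"z{z}_{suf}"] = []
        Xm, _, _ = self.wall_septum.marker_states()
        self._septum_pos_cache = Xm * units.M_TO_CM

        n_per_cycle = self.N // self.sample_every
        cycle_res: List[float] = []
        prev_p1: Optional[np.ndarray] = None
        converged = False
        t_start = time.time()
        for cyc in range(cfg.numerics.cycles):
            for _ in range(self.N):
                if self.step_count % self.sample_every == 0:
                    self._sample(rec)
                self.fsi_step()
            p1 = np.array(rec["z1_pTL"][-n_per_cycle:])
            if prev_p1 is not None and len(prev_p1) == len(p1):
                denom = np.linalg.norm(p1 - np.mean(p1)) or 1.0
                res = float(np.linalg.norm(p1 - prev_p1) / denom)
                cycle_res.append(res)
                if res < cfg.numerics.conv_tol and cyc + 1 >= cfg.numerics.min_cycles:
                    converged = True
            prev_p1 = p1
            if progress:
                q = np.array(rec["Q_in"][-n_per_cycle:])
                msg = (f"cycle {cyc + 1}/{cfg.numerics.cycles}  "
                       f"CO-so-far {np.mean(q) * units.MLPS_TO_LMIN:.2f} L/min")
                if cycle_res:
                    msg += f"  dP(cycle) {cycle_res[-1]:.2%}"
                msg += f"  [{time.time() - t_start:.0f}s]"
                print(msg, flush=True)
            if converged:
                break
        self._sample(rec)  # closing sample at the period boundary

        arrays = {k: np.asarray(v) for k, v in rec.items()}
        arts = RunArtifacts(
            t=arrays["t"],
            inlet={k: arrays[k] for k in ("pv", "Vv", "valve", "Q_in", "p_if")},
            zones={
                z: {suf: arrays[f"z{z}_{suf}"] for suf in
                    ("pTL", "QTL", "pFL", "QFL", "QFLf", "QFLr")}
                for z in self.zone_i
            },
            diagnostics={k: arrays[k] for k in ("mass", "max_v", "noslip")},
            septum_center=arrays["y_septum_mid"],
            wall_center=arrays["y_wall_mid"],
            cycle_residuals=cycle_res,
        )
        summary = self.summarize(arts, converged=converged)
        return summary, arts

    # ------------------------------------------------------------------
    def summarize(self, arts: RunArtifacts, converged=True) -> HemodynamicSummary:
        """Hemodynamic summary over the final cycles.

        The window covers the last two cardiac periods (when available):
        the false-lumen dynamics can settle into a two-beat (period-
        doubled) limit cycle, so single-cycle statistics would depend on
        the parity of the final beat.
        """
        n_per = self.N // self.sample_every
        n_cycles_run = (len(arts.t) - 1) // n_per
        w = 2 if n_cycles_run >= 3 else 1
        n = w * n_per
        sl = slice(-(n + 1), None)
        t = arts.t[sl]
        zones = {"TL": {}, "FL": {}}
        for z, zr in arts.zones.items():
            zones["TL"][z] = ZoneWaveform(z, "TL", t, zr["pTL"][sl], zr["QTL"][sl])
            if np.isfinite(zr["pFL"][sl]).all():
                zones["FL"][z] = ZoneWaveform(
                    z, "FL", t, zr["pFL"][sl], zr["QFL"][sl],
                    q_forward=zr["QFLf"][sl], q_reverse=zr["QFLr"][sl],
                )
        cfg = self.cfg
        meta = {
            "lambda": cfg.geometry.lambda_ratio,
            "HR": cfg.inlet.HR,
            "Ees": cfg.inlet.Ees,
            "Wo": cfg.womersley,
        }
        return summarize(zones, arts.inlet["Q_in"][sl], t, converged=converged,
                         meta=meta, n_cycles=w)


# ----------------------------------------------------------------------------
def run_simulation(config: RunConfig, outdir=None, progress=False):
    """Build and run one coupled simulation; optionally write artifacts.

    Returns ``(summary, artifacts)``.
    """
    sim = Simulation(config)
    summary, arts = sim.run(progress=progress)
    if outdir is not None:
        from dissectfsi.io import write_run

        write_run(outdir, config, summary, arts)
    return summary, arts


def sweep(config: RunConfig, lambdas=None, heart_rates=None, ees_values=None,
          outdir=None, progress=False):
    """Parameter sweep; one tidy summary row per combination.

    Failures of individual runs are recorded (row with ``error``) and the
    sweep continues.
    """
    import pandas as pd

    lambdas = list(lambdas) if lambdas else [config.geometry.lambda_ratio]
    heart_rates = list(heart_rates) if heart_rates else [config.inlet.HR]
    ees_values = list(ees_values) if ees_values else [config.inlet.Ees]
    rows = []
    for lam in lambdas:
        for hr in heart_rates:
            for ees in ees_values:
                cfg = copy.deepcopy(config)
                cfg.geometry.lambda_ratio = lam
                cfg.inlet.HR = hr
                cfg.inlet.Ees = ees
                try:
                    summary, _ = run_simulation(cfg, progress=progress)
                    rows.append(summary.as_row())
                except Exception as exc:  # noqa: BLE001 - record and continue
                    rows.append({"lambda": lam, "HR": hr, "Ees": ees,
                                 "error": str(exc)})
    table = pd.DataFrame(rows)
    if outdir is not None:
        import pathlib

        p = pathlib.Path(outdir)
        p.mkdir(parents=True, exist_ok=True)
        table.to_csv(p / "sweep.csv", index=False)
    return table
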