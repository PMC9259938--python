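"""Analytic benchmark cases for the solver components.

Each case carries its closed-form oracle and a tolerance; ``run_benchmark``
executes the case and reports the error norms.  The fluid cases run the
axisymmetric lattice solver in a rigid tube (plain BGK collision, halfway
bounce-back wall) against the Hagen-Poiseuille and Womersley solutions;
the structural cases check the Euler-Bernoulli closed forms; the
windkessel case checks the monotone diastolic decay of a pressurized
compliant segment through a resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
from scipy.special import jv

from dissectfsi.lbm import Lattice
from dissectfsi.wall import make_straight_wall


@dataclass(frozen=True)
class BenchmarkCase:
    name: str
    tolerance: float
    runner: Callable[[], float]

    def run(self):
        err = self.runner()
        return {"case": self.name, "error": err, "tolerance": self.tolerance,
                "passed": bool(err < self.tolerance)}


def poiseuille_error(R=16, tau=0.8, G=1.0e-5, n_steps=60000):
    """L2 error of steady pipe flow vs vx = G (R^2 - r^2) / (4 nu)."""
    nr = R + 1
    nx = 4
    nu = (tau - 0.5) / 3.0
    solid = np.zeros((nx, nr), bool)
    solid[:, -1] = True
    lat = Lattice(nx, nr, tau, solid=solid, axisym=True, periodic_x=True)
    fEx = np.full((nx, nr), G)
    for _ in range(n_steps):
        lat.step(fEx)
    lat.update_macro()
    lat.vx += 0.5 * np.where(lat.fluid, fEx, 0.0)
    r = np.arange(nr - 1) + 0.5
    v_ana = G / (4.0 * nu) * (R**2 - r**2)
    return float(np.linalg.norm(lat.vx[0, :-1] - v_ana) / np.linalg.norm(v_ana))


def womersley_error(R=16, tau=0.55, Wo=11.2, amplitude=0.02, n_cycles=25):
    """Cycle L2 error of oscillatory pipe flow vs the Bessel-function
    solution; run length covers the slow decay of the startup transient."""
    nr = R + 1
    nx = 4
    nu = (tau - 0.5) / 3.0
    omega = (Wo / R) ** 2 * nu
    N = int(round(2.0 * np.pi / omega))
    G = amplitude * omega
    solid = np.zeros((nx, nr), bool)
    solid[:, -1] = True
    lat = Lattice(nx, nr, tau, solid=solid, axisym=True, periodic_x=True)
    fEr = np.zeros((nx, nr))
    r = np.arange(nr - 1) + 0.5
    lam = 1j**1.5 * Wo
    prof = 1.0 - jv(0, lam * r / R) / jv(0, lam)
    num = den = 0.0
    for n in range(n_cycles * N):
        fEx = np.full((nx, nr), G * np.cos(omega * (n + 0.5)))
        lat.step(fEx, fEr)
        if n >= (n_cycles - 1) * N and n % max(N // 20, 1) == 0:
            lat.update_macro()
            t = n + 1
            v_num = lat.vx[0, :-1] + 0.5 * G * np.cos(omega * t)
            v_ana = np.real(G / (1j * omega) * prof * np.exp(1j * omega * t))
            num += float(np.sum((v_num - v_ana) ** 2))
            den += float(np.sum(v_ana**2))
    return float(np.sqrt(num / den))


def beam_static_error(L=0.29, EI=2.0e-7, w_load=5.0, n_el=64):
    """Midspan deflection of a simply supported beam vs 5 w L^4 / 384 EI."""
    wall = make_straight_wall(0.0, L, 0.0, L / n_el, Eh=0.0, EI=EI,
                              mass_per_area=2.2)
    F = np.zeros((wall.n_markers, 2))
    F[:, 1] = w_load
    wall.static_solve(wall.nodal_forces_from_markers(F))
    mid = wall.positions()[wall.n_nodes // 2, 1]
    ana = 5.0 * w_load * L**4 / (384.0 * EI)
    return float(abs(mid - ana) / ana)


def beam_modal_error(L=0.29, EI=2.0e-7, mass=2.2, n_el=64):
    """First modal frequency vs (pi/L)^2 sqrt(EI / (rho_s h))."""
    wall = make_straight_wall(0.0, L, 0.0, L / n_el, Eh=0.0, EI=EI,
                              mass_per_area=mass)
    om = wall.modal_frequencies(1)[0]
    ana = (np.pi / L) ** 2 * np.sqrt(EI / mass)
    return float(abs(om - ana) / ana)


def windkessel_decay_error():
    """Diastolic runoff analogue: a closed pressurized tube drains through
    a narrow outlet; the pressure must decay monotonically.  The reported
    error is the fraction of samples violating monotonicity (tolerance
    allows acoustic ripple)."""
    nx, nr = 120, 17
    solid = np.zeros((nx, nr), bool)
    solid[:, -1] = True
    # a narrow, viscous drain channel makes the discharge resistance-
    # dominated (overdamped), the analogue of diastolic runoff
    solid[80:, 2:] = True
    tau_f = np.full((nx, nr), 0.52)
    tau_f[75:, :] = 1.3
    lat = Lattice(nx, nr, tau_f, solid=solid, axisym=True)
    lat.outlet_open = True
    lat.rho_out = 1.0
    lat.initialize(rho0=np.where(np.arange(nx)[:, None] < 80, 1.01, 1.0))
    p = []
    for n in range(8000):
        lat.step()
        if n % 200 == 0:
            lat.update_macro()
            p.append(float(np.mean(lat.rho0[10:60, :10])))
    p = np.array(p)
    assert p[-1] < p[0]  # net discharge happened
    return float(np.mean(np.diff(p) > 1.0e-9))


CASES: Dict[str, BenchmarkCase] = {
    "poiseuille": BenchmarkCase("poiseuille", 0.01, poiseuille_error),
    "womersley": BenchmarkCase("womersley", 0.02, womersley_error),
    "beam_static": BenchmarkCase("beam_static", 0.01, beam_static_error),
    "beam_modal": BenchmarkCase("beam_modal", 0.02, beam_modal_error),
    "windkessel_decay": BenchmarkCase("windkessel_decay", 0.05, windkessel_decay_error),
}


def run_benchmark(name: str):
    """Execute one named benchmark; returns dict with error and pass flag."""
    if name not in CASES:
        raise KeyError(f"unknown benchmark case {name!r}; "
                       f"available: {sorted(CASES)}")
    return CASES[name].run()
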