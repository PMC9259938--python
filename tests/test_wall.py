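"""Structural wall model: statics, modes, dynamics, constraints."""

import numpy as np
import pytest

from dissectfsi.wall import WallModel, elasticity_sensitivity, make_straight_wall

L = 0.29
EI = 2.0e-7
MASS = 2.2


def bending_wall(n_el=64, EI_val=EI, mass=MASS, **kw):
    return make_straight_wall(0.0, L, 0.0, L / n_el, Eh=0.0, EI=EI_val,
                              mass_per_area=mass, **kw)


class TestStatics:
    def test_straight_wall_zero_residual(self):
        w = make_straight_wall(0.0, L, 0.01, L / 32, Eh=500.0, EI=EI,
                               mass_per_area=MASS)
        q0 = w.q.copy()
        w.static_solve(np.zeros(w.ndof))
        assert np.allclose(w.q, q0, atol=1e-9)

    def test_simply_supported_uniform_load(self):
        w = bending_wall()
        F = np.zeros((w.n_markers, 2))
        F[:, 1] = 5.0
        w.static_solve(w.nodal_forces_from_markers(F))
        mid = w.positions()[w.n_nodes // 2, 1]
        ana = 5.0 * 5.0 * L**4 / (384.0 * EI)
        assert mid == pytest.approx(ana, rel=0.01)

    def test_doubling_EI_halves_deflection(self):
        def midspan(EI_val):
            w = bending_wall(EI_val=EI_val)
            F = np.zeros((w.n_markers, 2))
            F[:, 1] = 1.0e-3  # small load: linear regime
            w.static_solve(w.nodal_forces_from_markers(F))
            return w.positions()[w.n_nodes // 2, 1]

        assert midspan(EI) / midspan(2 * EI) == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError):
            bending_wall(EI_val=-1.0)
        with pytest.raises(ValueError):
            make_straight_wall(0, L, 0, L / 8, Eh=0.0, EI=0.0, mass_per_area=1.0)


class TestDynamics:
    def test_first_modal_frequency(self):
        w = bending_wall()
        ana = (np.pi / L) ** 2 * np.sqrt(EI / MASS)
        assert w.modal_frequencies(1)[0] == pytest.approx(ana, rel=0.02)

    def test_rest_state_unchanged_by_stepping(self):
        w = make_straight_wall(0.0, L, 0.0, L / 16, Eh=100.0, EI=EI,
                               mass_per_area=MASS)
        q0 = w.q.copy()
        for _ in range(50):
            w.step(np.zeros(w.ndof), 1e-4)
        assert np.allclose(w.q, q0, atol=1e-12)
        assert np.abs(w.v).max() < 1e-12

    def test_free_vibration_energy_bounded(self):
        w = make_straight_wall(0.0, L, 0.0, L / 32, Eh=100.0, EI=EI,
                               mass_per_area=MASS)
        w.q[2::4] += 1e-3 * np.sin(np.pi * np.linspace(0, 1, w.n_nodes))
        for node in (0, w.n_nodes - 1):
            w.q[4 * node + 2] = w.q0[4 * node + 2]
        w.init_acceleration()
        E0 = w.energy()
        for _ in range(2000):
            w.step(np.zeros(w.ndof), 1e-4)
        assert w.energy() <= E0 * (1.0 + 1e-6)
        assert w.end_constraint_residual() == 0.0

    def test_sinusoidal_load_periodic_response(self):
        # pretension gives the membrane a restoring stiffness and light
        # structural damping lets the free-vibration transient decay,
        # leaving the periodic steady-state response of the drive
        w = make_straight_wall(0.0, L, 0.0, L / 32, Eh=265.0, EI=EI,
                               mass_per_area=MASS, stiffness_damping=0.05,
                               prestretch=0.05)
        dt, T = 2.0e-4, 0.05
        n_per = int(T / dt)
        amps = []
        F = np.zeros((w.n_markers, 2))
        for n in range(10 * n_per):
            F[:, 1] = 0.5 * np.sin(2 * np.pi * (n * dt) / T)
            w.step(w.nodal_forces_from_markers(F), dt)
            if n % n_per == n_per // 4:
                amps.append(w.positions()[w.n_nodes // 2, 1])
        # same phase sample every period once transients are gone
        assert amps[-1] == pytest.approx(amps[-2], rel=0.05)

    def test_prestretch_gives_baseline_tension(self):
        # a pretensioned membrane deflects less under the same load
        def midspan(pre):
            w = make_straight_wall(0.0, L, 0.0, L / 32, Eh=265.0, EI=EI,
                                   mass_per_area=MASS, prestretch=pre)
            F = np.zeros((w.n_markers, 2))
            F[:, 1] = 20.0
            w.static_solve(w.nodal_forces_from_markers(F))
            return w.positions()[w.n_nodes // 2, 1]

        assert midspan(0.05) < midspan(0.0)


class TestElasticitySensitivity:
    def test_waveform_shape_preserved_across_stiffness(self):
        """Higher elasticity -> smaller displacement, same waveform shape."""
        dt, T = 2.0e-4, 0.05

        def make_run(scale):
            w = make_straight_wall(0.0, L, 0.0, L / 24, Eh=100.0 * scale,
                                   EI=EI * scale, mass_per_area=MASS)
            F = np.zeros((w.n_markers, 2))
            t_out, y_out = [], []
            n_per = int(T / dt)
            for n in range(3 * n_per):
                F[:, 1] = 2.0 * max(np.sin(2 * np.pi * n * dt / T), 0.0) ** 2
                w.step(w.nodal_forces_from_markers(F), dt)
                if n >= 2 * n_per:
                    t_out.append(n * dt)
                    y_out.append(w.positions()[w.n_nodes // 2, 1])
            return t_out, y_out

        waves, corr = elasticity_sensitivity(make_run, [1.0, 2.0, 4.0])
        peaks = [np.max(np.abs(waves[s][1])) for s in (1.0, 2.0, 4.0)]
        assert peaks[0] > peaks[1] > peaks[2]
        assert np.min(corr) > 0.95
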