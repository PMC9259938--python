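"""Hemodynamic summary statistics vs closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dissectfsi import units
from dissectfsi.hemodynamics import (
    ZoneWaveform,
    cardiac_output,
    pulsatile_power,
    relative_pulse_pressure,
    reverse_flow_index,
    rfi_from_flow,
    rfi_per_cycle_mean,
)

T = 1.0
N = 400
TIME = np.linspace(0.0, T, N + 1)
RNG = np.random.default_rng(3)


class TestPulsatilePower:
    def test_constant_waveforms_have_no_pulsatile_power(self):
        p = np.full(N + 1, 95.0)
        q = np.full(N + 1, 90.0)
        ptot, pst, ppulse = pulsatile_power(p, q, TIME)
        assert ppulse == pytest.approx(0.0, abs=1e-10)
        assert ptot == pytest.approx(pst)

    def test_in_phase_harmonics_closed_form(self):
        a, b = 18.0, 120.0
        p = 90.0 + a * np.sin(2 * np.pi * TIME / T)
        q = 95.0 + b * np.sin(2 * np.pi * TIME / T)
        _, _, ppulse = pulsatile_power(p, q, TIME)
        assert ppulse == pytest.approx(0.5 * a * b * units.MMHG_MLPS_TO_MW, rel=1e-3)

    def test_matches_brute_force_riemann_sum(self):
        # independent oracle on a 10x finer grid
        t_f = np.linspace(0.0, T, 10 * N + 1)

        def wave(t):
            return (90 + 11 * np.sin(2 * np.pi * t) + 4 * np.cos(6 * np.pi * t),
                    80 + 60 * np.sin(2 * np.pi * t + 0.4))

        p, q = wave(TIME)
        pf, qf = wave(t_f)
        ptot, _, _ = pulsatile_power(p, q, TIME)
        oracle = np.sum(0.5 * (pf * qf)[1:] + 0.5 * (pf * qf)[:-1]) * (t_f[1] - t_f[0]) / T
        assert ptot == pytest.approx(oracle * units.MMHG_MLPS_TO_MW, rel=1e-3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            pulsatile_power(np.ones(5), np.ones(6), np.linspace(0, 1, 5))


class TestReverseFlowIndex:
    def test_pure_antegrade_flow_is_zero(self):
        q = 50.0 + 20.0 * np.sin(2 * np.pi * TIME)
        assert rfi_from_flow(q, TIME) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_splits_evenly(self):
        q = np.sin(2 * np.pi * TIME)
        assert rfi_from_flow(q, TIME) == pytest.approx(50.0, abs=1e-9)

    def test_matches_sign_split_brute_force(self):
        q = RNG.normal(size=N + 1) + 0.3
        fwd = np.trapezoid(np.maximum(q, 0.0), TIME)
        rev = -np.trapezoid(np.minimum(q, 0.0), TIME)
        oracle = 100.0 * rev / (rev + fwd)
        assert rfi_from_flow(q, TIME) == pytest.approx(oracle, abs=1e-12)

    def test_zero_flow_is_undefined(self):
        with pytest.raises(ValueError):
            rfi_from_flow(np.zeros(N + 1), TIME)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_uniform_rescaling(self, scale):
        q = np.sin(2 * np.pi * TIME) + 0.4
        assert rfi_from_flow(scale * q, TIME) == pytest.approx(
            rfi_from_flow(q, TIME), rel=1e-9
        )


def make_zone(zone, p):
    return ZoneWaveform(zone, "FL", TIME, np.asarray(p), np.zeros(N + 1))


class TestRelativePulsePressure:
    def test_identical_waveforms_give_zero(self):
        p = 80 + 20 * np.sin(2 * np.pi * TIME)
        zones = {4: make_zone(4, p), 5: make_zone(5, p)}
        assert relative_pulse_pressure(zones, 5, 4) == pytest.approx(0.0, abs=1e-12)

    def test_ten_percent_larger_pulse(self):
        p4 = 80 + 10 * np.sin(2 * np.pi * TIME)
        p5 = 80 + 11 * np.sin(2 * np.pi * TIME)
        zones = {4: make_zone(4, p4), 5: make_zone(5, p5)}
        assert relative_pulse_pressure(zones, 5, 4) == pytest.approx(0.1, rel=1e-6)

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_dimensionless_under_unit_change(self, factor):
        p4 = 80 + 10 * np.sin(2 * np.pi * TIME)
        p7 = 80 + 14 * np.sin(2 * np.pi * TIME)
        z1 = {4: make_zone(4, p4), 7: make_zone(7, p7)}
        z2 = {4: make_zone(4, factor * p4), 7: make_zone(7, factor * p7)}
        assert relative_pulse_pressure(z1, 7, 4) == pytest.approx(
            relative_pulse_pressure(z2, 7, 4), rel=1e-9
        )

    def test_zero_reference_pulse_rejected(self):
        zones = {4: make_zone(4, np.full(N + 1, 80.0)),
                 5: make_zone(5, 80 + np.sin(TIME))}
        with pytest.raises(ValueError):
            relative_pulse_pressure(zones, 5, 4)


class TestCardiacOutput:
    def test_constant_flow(self):
        assert cardiac_output(np.full(N + 1, 95.0), TIME) == pytest.approx(5.7)

    def test_zero_flow(self):
        assert cardiac_output(np.zeros(N + 1), TIME) == 0.0

    def test_pulsatile_mean(self):
        q = 95.0 + 40.0 * np.sin(2 * np.pi * TIME)
        assert cardiac_output(q, TIME) == pytest.approx(5.7, rel=1e-6)


class TestWindowedEstimators:
    """Per-beat indices over multi-cycle windows (beat-to-beat alternation)."""

    def test_rfi_per_cycle_mean_equals_mean_of_cycle_rfis(self):
        # two beats with different reversal fractions
        t = np.linspace(0.0, 2.0, 2 * N + 1)
        q = np.where(t < 1.0,
                     np.sin(2 * np.pi * t),             # RFI 50
                     1.0 + 0.5 * np.sin(2 * np.pi * t))  # RFI 0
        fwd, rev = np.maximum(q, 0.0), np.minimum(q, 0.0)
        got = rfi_per_cycle_mean(fwd, rev, t, 2)
        r1 = rfi_from_flow(q[:N + 1], t[:N + 1])
        r2 = rfi_from_flow(q[N:], t[N:])
        assert got == pytest.approx(0.5 * (r1 + r2), abs=1e-9)
        # the window-integral estimator volume-weights the beats instead
        assert got != pytest.approx(reverse_flow_index(fwd, rev, t), abs=1.0)

    def test_rfi_per_cycle_mean_single_cycle_reduces_to_rfi(self):
        q = np.sin(2 * np.pi * TIME / T)
        fwd, rev = np.maximum(q, 0.0), np.minimum(q, 0.0)
        assert rfi_per_cycle_mean(fwd, rev, TIME, 1) == pytest.approx(
            reverse_flow_index(fwd, rev, TIME), abs=1e-12)

    def test_pulse_pressure_per_cycle_mean_of_alternating_beats(self):
        t = np.linspace(0.0, 2.0, 2 * N + 1)
        p = np.where(t < 1.0,
                     90 + 10 * np.sin(2 * np.pi * t),
                     90 + 30 * np.sin(2 * np.pi * t))
        wf = ZoneWaveform(4, "FL", t, p, np.zeros_like(p))
        assert wf.pulse_pressure(2) == pytest.approx(0.5 * (20 + 60), rel=1e-3)
        # a max-min across both beats would give the larger beat only
        assert wf.pulse_pressure(1) == pytest.approx(60.0, rel=1e-3)
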