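"""Lattice-Boltzmann core: moment identities, analytic flows, conservation."""

import numpy as np
import pytest

from dissectfsi import lbm
from dissectfsi.benchmarks import poiseuille_error, womersley_error
from dissectfsi.lbm import Lattice

RNG = np.random.default_rng(42)


class TestEquilibrium:
    def test_rest_state_is_weighted_density(self):
        feq = lbm.equilibrium(1.3, 0.0, 0.0)
        assert np.allclose(feq, lbm.W * 1.3)

    def test_moment_identities(self):
        rho0, vx, vr = 1.02, 0.04, -0.03
        feq = lbm.equilibrium(rho0, vx, vr)
        assert feq.sum() == pytest.approx(rho0, rel=1e-14)
        # first moment returns the momentum (reference density 1)
        assert np.dot(lbm.EX, feq) == pytest.approx(vx, rel=1e-12)
        assert np.dot(lbm.ER, feq) == pytest.approx(vr, rel=1e-12)

    def test_high_speed_warns(self):
        with pytest.warns(RuntimeWarning):
            lbm.equilibrium(1.0, 0.2, 0.0)


class TestForcing:
    def test_zero_force_zero_term(self):
        F = lbm.forcing_term(0.02, 0.01, 0.0, 0.0, 0.8)
        assert np.all(F == 0.0)

    def test_tau_half_limit_vanishes(self):
        F = lbm.forcing_term(0.0, 0.0, 1e-3, 0.0, 0.5 + 1e-12)
        assert np.abs(F).max() < 1e-14

    def test_first_moment_matches_prefactor(self):
        tau, fx = 0.73, 2.5e-4
        F = lbm.forcing_term(0.0, 0.0, fx, 0.0, tau)
        assert np.dot(lbm.EX, F) == pytest.approx((1 - 0.5 / tau) * fx, rel=1e-12)
        assert np.dot(lbm.ER, F) == pytest.approx(0.0, abs=1e-18)


class TestAxisymmetricSource:
    def test_plug_flow_has_no_mass_source(self):
        H, Fx, Fr = lbm.axisymmetric_source(0.05, 0.0, 3.5, 0.7)
        assert np.all(H == 0.0)
        assert Fx == 0.0 and Fr == 0.0

    def test_mass_source_tracks_radial_velocity(self):
        H, _, _ = lbm.axisymmetric_source(0.0, 0.01, 2.5, 0.7)
        assert H.sum() == pytest.approx(-0.01 / 2.5, rel=1e-12)

    def test_axis_node_rejected(self):
        with pytest.raises(ValueError):
            lbm.axisymmetric_source(0.0, 0.0, 0.0, 0.7)


class TestVelocityGradients:
    def test_equilibrium_gives_zero_strain(self):
        feq = lbm.equilibrium(1.0, 0.03, 0.01)
        s_xr, dvxdx, dvrdr, _ = lbm.velocity_gradients(feq, feq, 0.8, np.zeros(5))
        assert abs(s_xr) < 1e-15 and abs(dvxdx) < 1e-15 and abs(dvrdr) < 1e-15

    def test_linear_radial_velocity_slope_exact(self):
        vr = 0.001 * np.arange(10.0)
        _, _, _, dvrdx = lbm.velocity_gradients(
            lbm.equilibrium(1.0, 0.0, 0.0), lbm.equilibrium(1.0, 0.0, 0.0),
            0.8, vr,
        )
        assert np.allclose(dvrdx, 0.001)

    def test_imposed_shear_recovered(self):
        # relax a shear perturbation one step and read the strain back
        gamma = 1e-4
        nx, nr = 8, 12
        r = np.arange(nr) + 0.5
        vx = gamma * np.tile(r, (nx, 1))
        lat = Lattice(nx, nr, 0.8, axisym=False, periodic_x=True)
        lat.initialize(vx=vx)
        for _ in range(3):
            lat.step()
        lat.update_macro()
        feq = lbm.equilibrium(lat.rho0, lat.vx, lat.vr)
        f = np.moveaxis(lat.f, 0, 0)
        s_xr, _, _, dvrdx = lbm.velocity_gradients(f, feq, 0.8, lat.vr)
        dvxdr = s_xr[3, 4:8] - dvrdx[3, 4:8]
        assert np.allclose(dvxdr, gamma, rtol=0.05)


class TestConservationAndFlows:
    def test_rest_fluid_is_fixed_point(self):
        lat = Lattice(12, 8, 0.8, axisym=False, periodic_x=True)
        f0 = lat.f.copy()
        for _ in range(20):
            lat.step()
        assert np.allclose(lat.f, f0, atol=1e-15)

    def test_mass_conserved_in_closed_box(self):
        # closed rigid box (bounce-back frame), planar transport core
        nx, nr = 24, 16
        solid = np.zeros((nx, nr), bool)
        solid[0, :] = solid[-1, :] = solid[:, 0] = solid[:, -1] = True
        lat = Lattice(nx, nr, 0.6, solid=solid, axisym=False)
        rho = 1.0 + 0.01 * RNG.random((nx, nr))
        vx = 0.01 * np.sin(2 * np.pi * np.arange(nx)[:, None] / nx) * np.ones((1, nr))
        lat.initialize(rho0=rho, vx=vx)
        m0 = lat.mass()
        for _ in range(1000):
            lat.step()
        assert abs(lat.mass() - m0) / m0 < 1e-10

    def test_viscosity_recovery_from_decay(self):
        # first Bessel mode in a rigid pipe decays at nu * (j01 / R)^2
        from scipy.special import jn_zeros, j0

        R, tau = 16, 0.8
        nu = (tau - 0.5) / 3.0
        nr, nx = R + 1, 4
        solid = np.zeros((nx, nr), bool)
        solid[:, -1] = True
        lat = Lattice(nx, nr, tau, solid=solid, axisym=True, periodic_x=True)
        j01 = jn_zeros(0, 1)[0]
        r = np.arange(nr) + 0.5
        v0 = 1e-4 * j0(j01 * r / R)
        lat.initialize(vx=np.tile(v0, (nx, 1)))
        n_steps = 2000
        for _ in range(n_steps):
            lat.step()
        lat.update_macro()
        amp = lat.vx[0, 0] / v0[0]
        rate = -np.log(amp) / n_steps
        assert rate == pytest.approx(nu * (j01 / R) ** 2, rel=0.02)

    def test_poiseuille_profile(self):
        assert poiseuille_error(R=16, n_steps=40000) < 0.01

    def test_grid_convergence_order(self):
        e_coarse = poiseuille_error(R=8, n_steps=20000)
        e_fine = poiseuille_error(R=16, n_steps=60000)
        order = np.log2(e_coarse / e_fine)
        assert order > 1.8

    def test_womersley_profile(self):
        assert womersley_error(Wo=11.2) < 0.02

    def test_divergence_detection(self):
        lat = Lattice(8, 8, 0.8, axisym=False, periodic_x=True)
        lat.f[0, 2, 2] = np.nan
        with pytest.raises(FloatingPointError):
            for _ in range(4):
                lat.step()
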