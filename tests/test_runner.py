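"""Run orchestration: configs, benchmarks registry, determinism, smoke run."""

import numpy as np
import pytest

from dissectfsi.benchmarks import CASES, run_benchmark
from dissectfsi.config import RunConfig, desk_scale_config
from dissectfsi.simulation import Simulation


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = desk_scale_config(**{"geometry.lambda_ratio": 0.4, "inlet.HR": 72.0})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        cfg2 = RunConfig.from_yaml(str(path))
        assert cfg2.to_dict() == cfg.to_dict()

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            desk_scale_config(**{"geometry.not_a_field": 1.0})
        with pytest.raises(KeyError):
            desk_scale_config(**{"lambda_ratio": 1.0})

    def test_tau_validation(self):
        cfg = desk_scale_config()
        cfg.numerics.steps_per_cycle = 5  # huge dt -> tau far above 1.5
        with pytest.raises(ValueError):
            cfg.validate()

    def test_derived_scales_consistent(self):
        cfg = desk_scale_config()
        assert cfg.dx_cm == pytest.approx(2.0 / 16.0)
        nu_lat = (cfg.tau - 0.5) / 3.0
        assert nu_lat == pytest.approx(cfg.nu_lattice, rel=1e-12)
        # the baseline matches the clinical comparison condition
        assert cfg.womersley == pytest.approx(11.2, rel=0.005)


class TestBenchmarks:
    def test_registry_contains_all_cases(self):
        assert set(CASES) == {"poiseuille", "womersley", "beam_static",
                              "beam_modal", "windkessel_decay"}

    def test_unknown_case_rejected(self):
        with pytest.raises(KeyError):
            run_benchmark("lid_driven_cavity")

    def test_beam_cases_pass(self):
        for name in ("beam_static", "beam_modal"):
            res = run_benchmark(name)
            assert res["passed"], res

    def test_windkessel_decay_monotone(self):
        res = run_benchmark("windkessel_decay")
        assert res["passed"], res


class TestCoupledRunner:
    def test_short_run_is_deterministic(self):
        def state_after(n):
            sim = Simulation(desk_scale_config())
            for _ in range(n):
                sim.fsi_step()
            return sim.lat.f.copy(), sim.wall_septum.q.copy()

        f1, q1 = state_after(300)
        f2, q2 = state_after(300)
        assert np.array_equal(f1, f2)
        assert np.array_equal(q1, q2)

    def test_smoke_run_first_beat_onset(self):
        """A short stretch of the coupled model runs without incident and
        the LV pressurizes toward valve opening."""
        sim = Simulation(desk_scale_config())
        p0 = sim.inlet.pv
        for _ in range(800):
            sim.fsi_step()
        assert np.isfinite(sim.lat.f).all()
        assert sim.inlet.pv > p0            # isovolumic contraction under way
        assert sim.coupling.last_residual < 1e-8
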