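"""Geometry construction, measurement stations and the Womersley number."""

import math

import numpy as np
import pytest

from dissectfsi.config import GeometryParams, RunConfig
from dissectfsi.geometry import (
    DissectionGeometry,
    build_dissection,
    womersley_number,
    zone_stations,
)


def make_geom(**kw):
    return build_dissection(GeometryParams(**kw))


class TestBuildDissection:
    @pytest.mark.parametrize(
        "lam, graft_len",
        [(0.13, 3.77), (0.26, 7.54), (0.40, 11.6), (0.53, 15.37), (0.66, 19.14)],
    )
    def test_graft_length_follows_ratio(self, lam, graft_len):
        g = make_geom(lambda_ratio=lam)
        got = g.graft_span[1] - g.graft_span[0]
        assert got == pytest.approx(graft_len, abs=0.005)

    def test_full_coverage_ratio_one(self):
        g = make_geom(lambda_ratio=1.0)
        assert g.graft_span[1] - g.graft_span[0] == pytest.approx(g.L_septum)

    def test_graft_seals_proximal_tear(self):
        g = make_geom(lambda_ratio=0.13)
        assert g.graft_span[0] == g.septum_span[0]
        assert g.graft_span[1] >= g.tear_proximal[1]

    @pytest.mark.parametrize("lam", [0.0, -0.2, 1.2])
    def test_invalid_ratio_rejected(self, lam):
        with pytest.raises(ValueError):
            make_geom(lambda_ratio=lam)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ValueError):
            make_geom(r_TL=1.2)

    def test_nesting_of_coverage(self):
        lams = [0.13, 0.26, 0.40, 0.53, 0.66]
        spans = [make_geom(lambda_ratio=v).graft_span for v in lams]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 <= a0 and b1 > a1

    def test_serialization_roundtrip_exact(self):
        g = make_geom(lambda_ratio=0.4)
        g2 = DissectionGeometry.from_json(g.to_json())
        assert g2 == g


class TestZoneStations:
    def test_count_and_ordering(self):
        g = make_geom()
        zs = zone_stations(g)
        assert len(zs) == 7
        fl = [z for z in zs if z.lumen == "FL"]
        assert [z.zone for z in fl] == [4, 5, 6, 7]
        xs = [z.x for z in fl]
        assert all(a < b for a, b in zip(xs, xs[1:]))

    def test_stations_inside_physical_aorta(self):
        g = make_geom()
        for z in zone_stations(g):
            assert 0.0 < z.x < g.L_aorta

    def test_override_snaps_to_lattice(self):
        cfg = RunConfig()
        dx = cfg.dx_cm
        g = build_dissection(cfg, stations={4: 13.03})
        z4 = next(z for z in g.zone_stations if z.zone == 4)
        assert z4.x == pytest.approx(round(13.03 / dx) * dx)
        assert (z4.x / dx) == pytest.approx(round(z4.x / dx))


class TestWomersley:
    def test_inversion_matches_clinical_value(self):
        # independent oracle: invert Wo(HR) numerically for Wo = 11.2
        from scipy.optimize import brentq

        rho, mu = 1060.0, 3.5e-3
        hr = brentq(lambda h: womersley_number(1.0, h, rho, mu) - 11.2, 1.0, 500.0)
        assert womersley_number(1.0, hr, rho, mu) == pytest.approx(11.2, rel=1e-10)
        # alpha = Wo^2 mu / (r^2 rho) gives the same heart rate in closed form
        alpha = 11.2**2 * mu / (0.01**2 * rho)
        assert hr == pytest.approx(alpha * 60.0 / (2.0 * math.pi), rel=1e-8)

    def test_viscosity_scaling(self):
        w1 = womersley_number(1.0, 60.0, 1060.0, 3.5e-3)
        w2 = womersley_number(1.0, 60.0, 1060.0, 7.0e-3)
        assert w2 == pytest.approx(w1 / math.sqrt(2.0), rel=1e-12)

    def test_low_heart_rate_limit(self):
        assert womersley_number(1.0, 1e-9, 1060.0, 3.5e-3) < 1e-3
        with pytest.raises(ValueError):
            womersley_number(1.0, 0.0, 1060.0, 3.5e-3)
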