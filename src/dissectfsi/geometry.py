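"""Idealized axisymmetric dissection geometry.

The dissected aorta is modeled in the (x, r) half-plane: the true lumen (TL)
is the inner channel r < r_TL, the false lumen (FL) is the annulus
r_TL < r < r_aorta formed uniformly around it, and the two communicate only
through the proximal and distal tears - axial openings at the two ends of
the dissected segment.  The FL is closed by radial end caps at both ends of
the dissected segment.  The endograft is a rigid cylinder at r = r_TL that
starts at the proximal end of the dissected segment and seals the proximal
tear; its length is lambda * L_septum.  Beyond x = L_aorta the domain
continues into the extension-tube outflow model: an elastic segment followed
by a rigid contraction of radius ratio kappa and an open end.

Seven measurement stations ("zones") are defined: zone 1 in the TL near the
aortic root, zones 2-3 in the TL at the tears, zones 4-7 in the FL ordered
proximal to distal along the septum.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

from dissectfsi.config import GeometryParams, RunConfig, womersley_from_physical


@dataclass(frozen=True)
class ZoneStation:
    zone: int          #: zone id, 1-7
    x: float           #: axial coordinate, cm
    lumen: str         #: "TL" or "FL"


@dataclass
class DissectionGeometry:
    """Axial layout of the dissection model (all lengths in cm)."""

    L_aorta: float
    L_septum: float
    r_aorta: float
    r_TL: float
    septum_span: tuple          #: (start, end) of the dissected segment
    tear_proximal: tuple        #: axial interval of the proximal tear opening
    tear_distal: tuple          #: axial interval of the distal tear opening
    graft_span: tuple           #: axial interval of the rigid endograft
    lambda_ratio: float
    L_boundary: float
    L_elastic_out: float
    L_taper_out: float
    kappa: float
    zone_stations: tuple        #: 7 ZoneStation entries

    @property
    def L_total(self) -> float:
        """Domain length including the outflow extension."""
        return self.L_aorta + self.L_boundary

    @property
    def flexible_septum_span(self) -> tuple:
        """Axial span of the septum that is free to move (not graft-covered)."""
        start = max(self.tear_proximal[1], self.graft_span[1])
        return (start, self.tear_distal[0])

    @property
    def elastic_wall_span(self) -> tuple:
        """Axial span of the elastic outer wall (aorta + elastic extension)."""
        return (0.0, self.L_aorta + self.L_elastic_out)

    @property
    def contraction_start(self) -> float:
        return self.L_aorta + self.L_elastic_out

    @property
    def r_contraction(self) -> float:
        return self.kappa * self.r_aorta

    # ----- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_stations"] = [dataclasses.asdict(z) for z in self.zone_stations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DissectionGeometry":
        d = dict(d)
        d["zone_stations"] = tuple(ZoneStation(**z) for z in d["zone_stations"])
        for key in ("septum_span", "tear_proximal", "tear_distal", "graft_span"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DissectionGeometry":
        return cls.from_dict(json.loads(text))


def womersley_number(r_cm: float, HR_bpm: float, rho: float, mu: float) -> float:
    """Womersley number Wo = r*sqrt(alpha*rho/mu) with alpha = 2*pi*HR/60."""
    if HR_bpm <= 0.0:
        raise ValueError("heart rate must be positive")
    alpha = 2.0 * math.pi * HR_bpm / 60.0
    return womersley_from_physical(r_cm, alpha, rho, mu)


def _snap(x: float, dx: Optional[float]) -> float:
    """Round an axial coordinate to the nearest lattice plane."""
    if dx is None:
        return x
    return round(x / dx) * dx


def build_dissection(
    config: RunConfig | GeometryParams,
    stations: Optional[dict] = None,
    snap_dx: Optional[float] = None,
) -> DissectionGeometry:
    """Build and validate the dissection geometry.

    Parameters
    ----------
    config
        A full :class:`RunConfig` or just its :class:`GeometryParams`.
    stations
        Optional overrides ``{zone_id: x_cm}`` for the measurement stations.
    snap_dx
        If given, stations are rounded to the nearest multiple of ``snap_dx``
        (the lattice spacing).  When ``config`` is a RunConfig its own lattice
        spacing is used by default.
    """
    if isinstance(config, RunConfig):
        g = config.geometry
        if snap_dx is None:
            snap_dx = config.dx_cm
    else:
        g = config

    if not (0.0 < g.lambda_ratio <= 1.0):
        raise ValueError(f"lambda_ratio must be in (0, 1], got {g.lambda_ratio}")
    if g.r_TL >= g.r_aorta or g.r_TL <= 0.0:
        raise ValueError("require 0 < r_TL < r_aorta")
    for name in ("L_aorta", "L_septum", "r_aorta", "tear_width", "L_boundary"):
        if getattr(g, name) <= 0.0:
            raise ValueError(f"{name} must be positive")

    x0 = g.septum_start
    x1 = x0 + g.L_septum
    if x1 + 1.0 > g.L_aorta:
        raise ValueError("dissected segment extends past the aortic model")

    graft_len = g.lambda_ratio * g.L_septum
    if graft_len > g.L_septum:
        raise ValueError("graft longer than septum")
    graft_span = (x0, x0 + graft_len)
    tear_p = (x0, x0 + g.tear_width)
    tear_d = (x1 - g.tear_width, x1)
    # The graft must seal the proximal tear completely ...
    if graft_span[1] < tear_p[1]:
        raise ValueError("endograft too short to seal the proximal tear")
    # ... and may reach the distal tear only if it covers it entirely (lambda = 1).
    if tear_d[0] < graft_span[1] < tear_d[1]:
        raise ValueError("endograft partially covers the distal tear")

    default_stations = _default_stations(g)
    if stations:
        merged = {z.zone: z for z in default_stations}
        for zone_id, x in stations.items():
            if zone_id not in merged:
                raise KeyError(f"unknown zone id {zone_id}")
            merged[zone_id] = ZoneStation(zone_id, float(x), merged[zone_id].lumen)
        default_stations = tuple(merged[i] for i in sorted(merged))

    snapped = tuple(
        ZoneStation(z.zone, _snap(z.x, snap_dx), z.lumen) for z in default_stations
    )
    for z in snapped:
        if not (0.0 < z.x < g.L_aorta):
            raise ValueError(f"zone {z.zone} station x={z.x} outside the physical aorta")

    return DissectionGeometry(
        L_aorta=g.L_aorta,
        L_septum=g.L_septum,
        r_aorta=g.r_aorta,
        r_TL=g.r_TL,
        septum_span=(x0, x1),
        tear_proximal=tear_p,
        tear_distal=tear_d,
        graft_span=graft_span,
        lambda_ratio=g.lambda_ratio,
        L_boundary=g.L_boundary,
        L_elastic_out=g.L_elastic_out,
        L_taper_out=g.L_taper_out,
        kappa=g.kappa,
        zone_stations=snapped,
    )


def _default_stations(g: GeometryParams) -> tuple:
    """Default zone stations.

    Zone 1 sits in the TL 2 cm from the inlet; zones 2 and 3 at the proximal
    and distal tear midpoints in the TL; zones 4-7 at four equally spaced
    stations along the septum span in the FL (interior fractions 1/5 .. 4/5).
    """
    x0 = g.septum_start
    x1 = x0 + g.L_septum
    sep_lo = x0 + g.tear_width
    sep_hi = x1 - g.tear_width
    span = sep_hi - sep_lo
    fl = [sep_lo + span * k / 5.0 for k in (1, 2, 3, 4)]
    return (
        ZoneStation(1, 2.0, "TL"),
        ZoneStation(2, 0.5 * (x0 + x0 + g.tear_width), "TL"),
        ZoneStation(3, 0.5 * (x1 - g.tear_width + x1), "TL"),
        ZoneStation(4, fl[0], "FL"),
        ZoneStation(5, fl[1], "FL"),
        ZoneStation(6, fl[2], "FL"),
        ZoneStation(7, fl[3], "FL"),
    )


def zone_stations(geometry: DissectionGeometry) -> tuple:
    """The 7 labeled measurement stations of a built geometry."""
    return geometry.zone_stations
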