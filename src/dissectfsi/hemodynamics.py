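"""Hemodynamic summary statistics from zone waveforms.

All statistics are computed on an integer number of cardiac periods with
trapezoidal quadrature.  Unit conventions: pressures in mmHg, flows in ml/s,
powers in mW, cardiac output in L/min; the reverse flow index (RFI) and
relative pulse pressure (RPP) are dimensionless (RFI in percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from dissectfsi import units


@dataclass
class ZoneWaveform:
    """Waveforms at one measurement station over the final (periodic) cycles."""

    zone: int
    lumen: str
    t: np.ndarray                 #: time base, s, uniform, spanning k*T
    p: np.ndarray                 #: pressure, mmHg
    q: np.ndarray                 #: cross-section integrated flow, ml/s
    q_forward: Optional[np.ndarray] = None  #: antegrade part of the flow, ml/s
    q_reverse: Optional[np.ndarray] = None  #: retrograde part of the flow, ml/s

    def pulse_pressure(self, n_cycles: int = 1) -> float:
        """max(p) - min(p), averaged per cycle when the waveform spans
        several periods (beat-to-beat alternation would otherwise inflate
        the range by mixing extremes of different beats)."""
        if n_cycles <= 1:
            return float(np.max(self.p) - np.min(self.p))
        m = (len(self.p) - 1) // n_cycles
        pps = [float(np.max(self.p[k * m:(k + 1) * m + 1])
                     - np.min(self.p[k * m:(k + 1) * m + 1]))
               for k in range(n_cycles)]
        return float(np.mean(pps))


@dataclass
class HemodynamicSummary:
    P_total: float                #: mean total hydraulic power, mW
    P_steady: float               #: steady power, mW
    P_pulse: float                #: pulsatile power, mW
    CO: float                     #: cardiac output, L/min
    rfi: Dict[int, float]         #: RFI per FL zone, %
    rfi_fl_avg: float             #: mean RFI of zones 4-6, %
    pulse_pressure: Dict[int, float]   #: per zone, mmHg
    rpp: Dict[tuple, float]       #: |RPP| for zone pairs, dimensionless
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flatten to one tidy row (for the sweep results table)."""
        row = {
            "P_total_mW": self.P_total,
            "P_steady_mW": self.P_steady,
            "P_pulse_mW": self.P_pulse,
            "CO_L_min": self.CO,
            "RFI_FL_avg": self.rfi_fl_avg,
            "converged": self.converged,
        }
        row.update({f"RFI_zone{z}": v for z, v in self.rfi.items()})
        row.update({f"pp_zone{z}_mmHg": v for z, v in self.pulse_pressure.items()})
        row.update({f"RPP_{i}_{j}": v for (i, j), v in self.rpp.items()})
        row.update(self.meta)
        return row


def _check_shared_grid(t, *arrays):
    t = np.asarray(t, dtype=float)
    for a in arrays:
        if np.asarray(a).shape != t.shape:
            raise ValueError("waveforms must share one time grid")
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("time grid must be uniform")
    return t


def pulsatile_power(p, q, t):
    """Total, steady and pulsatile hydraulic power over one period.

    P_total = (1/T) int p q dt;  P_steady = mean(p) mean(q);
    P_pulse = P_total - P_steady.  p in mmHg, q in ml/s -> powers in mW.
    """
    t = _check_shared_grid(t, p, q)
    T = t[-1] - t[0]
    if T <= 0:
        raise ValueError("need a positive integration window")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p_total = np.trapezoid(p * q, t) / T
    p_mean = np.trapezoid(p, t) / T
    q_mean = np.trapezoid(q, t) / T
    p_steady = p_mean * q_mean
    c = units.MMHG_MLPS_TO_MW
    return p_total * c, p_steady * c, (p_total - p_steady) * c


def reverse_flow_index(q_forward, q_reverse, t):
    """RFI = |int Q_reverse| / (|int Q_reverse| + |int Q_forward|) * 100.

    ``q_forward``/``q_reverse`` are the antegrade/retrograde parts of the
    cross-section flow at each phase, obtained by integrating the positive
    and negative parts of the axial velocity profile (antegrade = toward the
    outlet).  For a uniform profile this reduces to the positive/negative
    parts of Q(t) itself.
    """
    t = _check_shared_grid(t, q_forward, q_reverse)
    fwd = abs(np.trapezoid(np.asarray(q_forward, dtype=float), t))
    rev = abs(np.trapezoid(np.asarray(q_reverse, dtype=float), t))
    tot = fwd + rev
    if tot == 0.0:
        raise ValueError("RFI undefined: zero total flow magnitude")
    return 100.0 * rev / tot


def rfi_from_flow(q, t):
    """RFI of a scalar flow waveform (uniform-profile shortcut)."""
    q = np.asarray(q, dtype=float)
    return reverse_flow_index(np.maximum(q, 0.0), np.minimum(q, 0.0), t)


def rfi_per_cycle_mean(q_forward, q_reverse, t, n_cycles):
    """Mean of the per-cycle RFIs over a window of ``n_cycles`` periods.

    The RFI is defined per cardiac cycle; when beats alternate, the
    per-beat mean is the faithful population statistic, whereas a single
    integral over the window would weight each beat by its flow volume
    and discount near-stagnant high-reversal beats (a different
    quantity).
    """
    if n_cycles <= 1:
        return reverse_flow_index(q_forward, q_reverse, t)
    m = (len(t) - 1) // n_cycles
    vals = [reverse_flow_index(q_forward[k * m:(k + 1) * m + 1],
                               q_reverse[k * m:(k + 1) * m + 1],
                               t[k * m:(k + 1) * m + 1])
            for k in range(n_cycles)]
    return float(np.mean(vals))


def relative_pulse_pressure(zones: Dict[int, ZoneWaveform], i: int, j: int,
                            n_cycles: int = 1) -> float:
    """|RPP(i, j)| = |pp_i - pp_j| / pp_j from final-cycle(s) pulse
    pressures."""
    pp_i = zones[i].pulse_pressure(n_cycles)
    pp_j = zones[j].pulse_pressure(n_cycles)
    if pp_j <= 0.0:
        raise ValueError(f"zone {j} has non-positive pulse pressure")
    return abs(pp_i - pp_j) / pp_j


def cardiac_output(q_inlet, t):
    """Mean inlet flow over the window (ml/s in, L/min out)."""
    t = _check_shared_grid(t, q_inlet)
    T = t[-1] - t[0]
    mean_q = np.trapezoid(np.asarray(q_inlet, dtype=float), t) / T
    return mean_q * units.MLPS_TO_LMIN


def summarize(
    zones: Dict[str, Dict[int, ZoneWaveform]],
    q_inlet: np.ndarray,
    t: np.ndarray,
    power_zone: int = 1,
    rfi_zones=(4, 5, 6),
    rpp_pairs=((4, 5), (4, 6), (4, 7)),
    converged: bool = True,
    meta: Optional[dict] = None,
    n_cycles: int = 1,
) -> HemodynamicSummary:
    """Full summary from TL/FL zone waveforms of the final cycle(s).

    ``zones`` maps lumen tag ("TL"/"FL") to per-zone waveforms spanning
    ``n_cycles`` periods.  Pulsatile power uses zone 1 in the TL; RFI
    averages FL zones 4-6; RPP compares FL pulse pressures against zone 4.

    Per-beat-defined indices (RFI, pulse pressure) are computed per cycle
    and averaged over the window; integral quantities (powers, CO)
    integrate over the whole window.  An even multi-cycle window gives
    well-defined statistics when the false-lumen dynamics show beat-to-
    beat alternation.
    """
    z1 = zones["TL"][power_zone]
    ptot, pst, ppulse = pulsatile_power(z1.p, z1.q, t)
    rfi = {}
    for z in rfi_zones:
        wf = zones["FL"][z]
        rfi[z] = rfi_per_cycle_mean(wf.q_forward, wf.q_reverse, t, n_cycles)
    pp = {z: wf.pulse_pressure(n_cycles) for z, wf in zones["FL"].items()}
    rpp = {}
    for i, j in rpp_pairs:
        # reported as |pp_i' - pp_j'|/pp_j with j the reference zone (4)
        rpp[(i, j)] = relative_pulse_pressure(zones["FL"], j, i, n_cycles)
    return HemodynamicSummary(
        P_total=ptot,
        P_steady=pst,
        P_pulse=ppulse,
        CO=cardiac_output(q_inlet, t),
        rfi=rfi,
        rfi_fl_avg=float(np.mean([rfi[z] for z in rfi_zones])),
        pulse_pressure=pp,
        rpp=rpp,
        converged=converged,
        meta=meta or {},
    )
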