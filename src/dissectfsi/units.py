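"""Unit conversion constants, kept in one place.

Internal solver units are lattice units (dx = dt = rho = 1).  Physical I/O
uses cm, s, mmHg, ml; powers are reported in mW.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_TO_M3 = 1.0e-6
M3_TO_ML = 1.0e6

CM_TO_M = 1.0e-2
M_TO_CM = 1.0e2

#: 1 mmHg * 1 ml/s expressed in mW (hydraulic power conversion)
MMHG_MLPS_TO_MW = MMHG_TO_PA * ML_TO_M3 * 1.0e3

MLPS_TO_LMIN = 60.0 / 1000.0
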