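"""Check the fluid and structural solvers against their closed forms.

Prints the error of each analytic benchmark next to its tolerance: steady
and oscillatory pipe flow (Hagen-Poiseuille, Womersley at Wo = 11.2) for
the axisymmetric lattice solver, and static deflection plus first modal
frequency of a simply supported beam for the wall model.
"""

from dissectfsi.benchmarks import CASES, run_benchmark

for name in CASES:
    res = run_benchmark(name)
    flag = "ok" if res["passed"] else "FAIL"
    print(f"{name:18s} error = {res['error']:.5f}  "
          f"(tolerance {res['tolerance']}) {flag}")
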