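"""Analytic solver-verification suite.

Every solver claim is anchored to closed-form references before dialyzer
predictions are trusted: Hagen-Poiseuille pressure drop and centreline
velocity for a closed membrane, the exactly linear no-flow diffusion slab,
and the Graetz mixed-cup decay rate against an independently computed
leading eigenvalue.
"""

import hollowfiber.benchmarks as bm

for entry in bm.verify():
    status = "PASS" if entry["passed"] else "FAIL"
    print(f"[{status}] {entry['name']:<24} measured={entry['measured']:12.6g} "
          f"reference={entry['reference']:12.6g} "
          f"rel_err={entry['rel_error']:.2e} (tol {entry['tolerance']:.0e})")
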