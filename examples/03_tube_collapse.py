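"""Collapse of an epithelial tube cross-section under three load scenarios.

Simulates an elastic ring (thickness t = 0.5 R, 100 elements) under (1) a
slowly ramped external pressure, (2) rigid clamps closing to a gap of 2.5 t,
and (3) linear lumen drainage, and reports where the hoop stress and
curvature localize in the collapsed equilibria.
"""

import numpy as np

from epitube.tube_collapse import (LoadScenario, MaterialParams,
                                   critical_pressure, make_ring,
                                   simulate_collapse)

mat = MaterialParams()  # E = 1, nu = 0.49, t/R = 0.5
ring = make_ring(radius=1.0, n=100, mat=mat)

res = simulate_collapse(ring, mat, LoadScenario(kind="pressure"),
                        max_time=4000, speed_tol=1e-6)
pcr = critical_pressure(mat, 1.0)
print(f"pressure scenario: buckling at dP = {res.buckling_pressure:.4f} E "
      f"(thin-ring prediction 3 E* I / R^3 = {pcr:.4f} E)")

for kind in ("clamps", "volume"):
    ring = make_ring(radius=1.0, n=100, mat=mat)
    res = simulate_collapse(ring, mat, LoadScenario(kind=kind),
                            max_time=4000, speed_tol=1e-6)
    s = res.surface_stress
    k = np.abs(res.curvature)
    print(f"{kind} scenario: enclosed area {res.enclosed_area / np.pi:.2f} "
          f"of initial; surface hoop stress peak/median = "
          f"{s.max() / np.median(s):.1f}; curvature peak/median = "
          f"{k.max() / np.median(k):.1f}")

# In both constrained scenarios the stress concentrates almost entirely in
# the two high-curvature lobes of the collapsed cross-section — a line-like
# pattern along the tube, not the uniform circumferential cue that straight
# biased outgrowth would require.
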