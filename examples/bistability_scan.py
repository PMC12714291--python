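"""Brute-force attractor scan: firing/rest bistability of class-II Morris-Lecar.

At each constant hold current the model is integrated from an
equilibrium-adjacent and from a spike-adjacent initial condition; when the
two settle on different attractors the cell is bistable, the signature of a
subcritical Hopf bifurcation with a fold of limit cycles below it.
"""

import numpy as np

from rampclamp import attractor_scan, get_model

model = get_model("morris_lecar_II")
grid = np.arange(100.0, 171.0, 2.0)
scan = attractor_scan(model, grid, T=2000.0, n_inits=2)

counts = {c: scan.classification.count(c) for c in ("rest", "spiking", "bistable")}
print(f"scanned Ih in [{grid[0]:.0f}, {grid[-1]:.0f}] pA: {counts}")
for lo, hi in scan.bistable_intervals:
    print(f"bistable window: [{lo:.0f}, {hi:.0f}] pA (midpoint {(lo + hi) / 2:.0f} pA)")
spk = ~np.isnan(scan.V_min)
if spk.any():
    print(f"firing envelope spans {scan.V_min[spk].min():.0f} to "
          f"{scan.V_max[spk].max():.0f} mV where cycles exist")
print()
print("Inside the window a stable spiking cycle coexists with a stable rest")
print("state: a slow current ramp passes it with hysteresis.")
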