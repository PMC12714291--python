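"""How closely the slow voltage-clamp ramp traces the equilibrium I-V curve.

A proportional clamp (gain gc) ramps the hold voltage at 1.83 mV/s across
the full S-curve of the class-I Morris-Lecar model, middle (CC-unstable)
branch included.  The measured feedback current is compared with the
analytic equilibrium current at the recorded membrane potential; the
deviation is first order in the ramp speed.
"""

import numpy as np

from rampclamp import VCProtocol, get_model, simulate_vc

model = get_model("morris_lecar_I")
rec = simulate_vc(model, VCProtocol(Vh_start=-80.0, Vh_end=30.0,
                                    ramp_speed=1.83e-3, gc=40.0))
mask = rec.t > 0.02 * rec.t[-1]
ieq = np.asarray(model.equilibrium_current(rec.V))
dev = np.abs(rec.I - ieq)[mask]
rng = np.ptp(ieq[mask])

print(f"ramp duration {rec.t[-1] / 1000:.0f} s, {len(rec.t)} samples at 20 kHz")
print(f"traversed current range: {rng:.0f} pA")
print(f"max |Ivc - I_eq(V)|: {dev.max():.3f} pA  ({100 * dev.max() / rng:.3f}% of range)")
print()
print("The clamp reads out the full steady-state curve - hidden branch and all -")
print("with a bias far below the percent scale set by the slow/fast timescale ratio.")
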