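"""Ground-truth steady-state bifurcation diagram of a class-I Morris-Lecar cell.

The equilibrium current I_eq(V) (all gates at steady state) is sampled on a
voltage grid; its folds bound the S-shaped multivalued region and the Hopf
candidate marks where the depolarized branch regains stability (the
depolarization block).
"""

from rampclamp import get_model, steady_state_curve

model = get_model("morris_lecar_I")
curve = steady_state_curve(model, V_range=(-80.0, 30.0), n_points=2001, gc=40.0)

n_unstable = int((~curve.stable_cc).sum())
print(f"sampled {len(curve.V)} points on V in [-80, 30] mV")
print(f"CC-unstable points: {n_unstable} ({100 * n_unstable / len(curve.V):.1f}% of curve)")
print(f"VC-stable everywhere at gc = {curve.gc:.0f} nS: {bool(curve.stable_vc.all())}")
for v, i in curve.folds:
    print(f"fold (saddle-node) at V = {v:7.2f} mV, I = {i:7.2f} pA")
for v, i in curve.hopf:
    print(f"Hopf candidate    at V = {v:7.2f} mV, I = {i:7.2f} pA")
print()
print("The two folds delimit the middle branch that is invisible to a current")
print("clamp; the Hopf current approximates the depolarization block I_db.")
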