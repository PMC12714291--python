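"""End to end: noisy synthetic recordings to a labeled experimental diagram.

Generates one synthetic "cell" (class-I Morris-Lecar with current noise,
dropout pulses and 2% conductance drift), runs the full slow-ramp VC and CC
protocols on it, and assembles the experimental bifurcation diagram:
smoothed S-curve, stability labels from the two evidence rules, fold
markers, depolarization block, drift and bias diagnostics.
"""

from rampclamp import DriftConfig, assemble_diagram, build_vc_curve, make_fixture

fx = make_fixture("morris_lecar_I", drift=DriftConfig(0.02), seed=42)
curve = build_vc_curve(fx.vc)
diag = assemble_diagram(curve, fx.cc)

print(f"VC run: {len(fx.vc.t)} samples; CC run: {len(fx.cc.t)} samples")
for v, i in diag.labeling.folds:
    print(f"fold marker at Vh = {v:7.2f} mV, I = {i:6.1f} pA")
print("ground truth:   "
      + "; ".join(f"Vh = {v + i / fx.truth.gc:7.2f} mV, I = {i:6.1f} pA"
                  for v, i in fx.truth.folds))
print(f"firing onset {diag.onset_I:.0f} pA, depolarization block I_db = {diag.I_db:.0f} pA")
for seg in diag.labeling.segments(curve.Vh, curve.I_sm):
    lo, hi = seg["Vh_mV"]
    print(f"  {seg['label']:>12} ({seg['basis']:<20}) Vh {lo:7.2f} .. {hi:7.2f} mV")
print(f"drift metric {diag.drift_metric:.2f} pA, "
      f"{len(diag.dropouts)} dropout events flagged")
print(f"ramp biases: VC {diag.bias_vc_mV:.3f} mV, CC {diag.bias_cc_mV:.3f} mV")
print()
print("The slope-labeled segment is the hidden middle branch; its boundaries")
print("recover the true folds to within a couple of millivolts despite noise,")
print("dropouts and the 2% conductance drift (truth refers to the undrifted cell).")
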