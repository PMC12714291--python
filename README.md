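# rampclamp

Slow-ramp voltage-clamp / current-clamp simulation and analysis for building
**experimental steady-state bifurcation diagrams of neurons, including their
dynamically unstable ("hidden") branches**.

## The problem

A neuron driven by a constant current `I_ext` has a family of stationary
states described by its steady-state I–V relation

```
I_eq(V) = Σ_j I_j(x_∞,j(V), V),        I_j = g_j · Π x^p · (V − E_j)
```

with all channel gates `x` at their voltage-dependent steady states.  Read
as `V(I)` this curve is S-shaped for many cells: the middle branch consists
of *unstable* equilibria that an ordinary current-clamp (CC) experiment can
never show — the cell jumps from rest to spiking right across them.  Yet the
same points are fixed points of the *voltage-clamped* (VC) membrane: a
feedback current `I_vc = g_c (V_h − V)` stabilizes every branch.  Ramping
the hold voltage `V_h` slowly (1.83 mV/s, a factor ε = 10⁻² below the fast
membrane scale) therefore traces the whole curve, hidden branch included,
with a bias that is first order in the ramp speed:

```
|bias| ≈ I_eq'(V) · V̇ · τ½ / ln 2
```

where τ½ is the half-decay time of clamp transients.  Overlaying the slow
VC run with a slow CC current ramp (≈7 pA/s) on the same cell yields an
experimental bifurcation diagram: negative slope of the smoothed VC curve
proves instability topologically, firing in the CC run at matching currents
marks unstable foci circumstantially, folds are saddle-node points, and the
firing collapse at the depolarization block `I_db` marks a Hopf bifurcation.

`rampclamp` implements this protocol end to end *in silico* for
conductance-based models — the Morris–Lecar model (class-I and class-II
excitability) and the Wang–Buzsáki interneuron model are built in — plus the
full data pipeline that turns raw `(t, V, I)` recordings, synthetic or
experimental, into labeled diagrams.  It is aimed at electrophysiologists
planning or interpreting such slow-ramp experiments and at modelers
validating cell models against them.

## What's inside

| module | contents |
| --- | --- |
| `rampclamp.models` | declarative conductance-based models, gating laws, `I_eq(V)` |
| `rampclamp.protocols` | slow-ramp VC/CC and step protocols; white-noise + dropout disturbances (compiled fixed-step stochastic integrator) |
| `rampclamp.ground_truth` | steady-state curves with CC/VC eigenvalues, folds, Hopf candidates; brute-force attractor scans (bistability, `I_db`) |
| `rampclamp.analysis` | moving-median smoothing, slope/oscillation stability labels, spike & block detection, slow-phase masks, (V, V′) embeddings, τ½ fits, ramp-bias estimates, dropout detection, diagram assembly |
| `rampclamp.fixtures` | seeded synthetic VC/CC/step bundles with known ground truth and conductance drift |
| `rampclamp.io`, `rampclamp.config`, `rampclamp.cli` | TSV+JSON recording exchange, YAML run configs, thin `rampclamp` command |

## Worked example

```bash
python examples/full_pipeline.py
```

generates one synthetic class-I cell (20 kHz, current noise, dropout pulses,
2 % conductance drift), runs both slow-ramp protocols and assembles the
diagram:

```
fold marker at Vh =  -24.71 mV, I =   42.3 pA
fold marker at Vh =   -8.58 mV, I =   22.3 pA
ground truth:   Vh =  -26.66 mV, I =   42.0 pA; Vh =   -8.46 mV, I =   23.2 pA
firing onset 43 pA, depolarization block I_db = 244 pA
        stable (none                ) Vh  -80.00 ..  -24.71 mV
      unstable (slope               ) Vh  -24.71 ..   -8.58 mV
  undetermined (none                ) Vh   -8.58 ..   -1.47 mV
      unstable (oscillation-evidence) Vh   -1.47 ..   14.31 mV
        stable (none                ) Vh   14.31 ..   30.00 mV
drift metric 0.47 pA, 26 dropout events flagged
ramp biases: VC 0.198 mV, CC 0.516 mV
```

The brown "slope" segment is the hidden middle branch between the two folds;
the yellow "undetermined" stretch is where a single up-ramp provides no
stability evidence either way.  The other examples each demonstrate one
capability (`steady_state_curve`, `vc_tracking`, `bias_estimates`,
`bistability_scan`, `step_transient`), and the same steps are scriptable:

```bash
rampclamp ground-truth --model morris_lecar_I --out truth.tsv
rampclamp fixtures --model morris_lecar_I --seed 1 --out cell1/
rampclamp analyze --vc cell1/vc.tsv --cc cell1/cc.tsv --out cell1/diagram
```

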