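# Methods

## Model class and units

All cells are single-compartment conductance-based membranes,

    C dV/dt = −Σ_j I_j(x_j, V) + I_ext,     τ_j(V) dx_j/dt = φ_j (x_∞,j(V) − x_j),

with currents `I_j = g_j · Π x^p · (V − E_j)`.  Units are fixed package-wide
to mV, ms, pA, nS and pF, which closes the equation dimensionally
(pA/pF = mV/ms).  Ramp speeds quoted per second on the bench
(mV/s, pA/s) are converted at the config layer.

Two deliberate readings of the printed model definitions are baked in and
worth stating explicitly:

* **Morris–Lecar recovery time.** The recovery gate uses
  `τ_w(V) = 1 / cosh((V − V3)/(2 V4))` — the canonical reciprocal-cosh
  form — so `dw/dt = φ (w_∞ − w) · cosh((V − V3)/(2 V4))`.
* **Wang–Buzsáki sodium gate.** Activation `m` is instantaneous and enters
  as `m_∞(V)³`; only inactivation `h` and the potassium gate `n` are state
  variables, giving a three-dimensional model `(V, h, n)`.  The inactivation
  opening rate is `α_h = 0.07·exp(−0.05(V + 58))`.  Rate functions with
  removable singularities (`α_m` at V = −35 mV, `α_n` at V = −34 mV) are
  evaluated by their limits.

The Wang–Buzsáki parameters are used exactly as tabulated (C = 1 pF,
conductances in nS), so absolute current scales differ from the classical
per-area (µS/cm²) formulation of that model; all derived statements are
scale-consistent within this convention.

## Protocols

* **VC ramp**: `I_ext = g_c (V_h − V)` with `V_h` ramping linearly at
  1.83 mV/s by default (ε = 10⁻² of the 0.183 mV/ms fast scale), from −80
  to +30 mV.  The recorded current is the clean feedback term
  `I_vc = g_c (V_h − V)`; injected disturbances act on the membrane and
  reach the recording only through V, as in a real clamp.  Default gains:
  40 nS (Morris–Lecar class I), 150 nS (class II), 20 nS (Wang–Buzsáki); a
  config may instead give a feedback resistor, `g_c = 1/R_f`.
* **CC ramp**: `I_ext = I_h(t)` at 7 pA/s by default, 0 → 420 pA in 60 s.
* **Step**: baseline → 200 pA between 0.1 s and 1.6 s by default, for
  transient (τ½) calibration.

Every run starts from a state relaxed for 500 ms at the protocol's start
value, so recordings begin after initial transients.  The sampling grid is
0.05 ms (20 kHz).

**Integration.**  Deterministic runs use the adaptive stiff solver (LSODA,
rtol 1e−8, atol 1e−10) evaluated on the sample grid.  Runs with
disturbances use a fixed-step Euler–Maruyama scheme at the sampling
interval (numba-compiled; optionally subdivided), with per-step current
noise of standard deviation `noise_sd/√dt` plus Poisson-timed square
dropout pulses.  The disturbance realization is drawn once per run from a
seeded generator, so identical seeds give bit-identical recordings.  The
two integrators agree to a few µV on clean runs (tested).

## Ground truth

The steady-state curve is sampled on a uniform V grid (2001 points over
[−80, 30] mV by default): `I_eq(V)` is single-valued in V, so branches that
are multivalued in I need no arclength continuation.  Each point carries
eigenvalues of the fast-subsystem Jacobian under CC (`I_ext` constant) and
under VC (`I_ext = g_c(V_h − V)`, which subtracts `g_c/C` from the ∂V̇/∂V
entry).  Jacobians are central finite differences of the right-hand side
(step 1e−6, scaled), one code path for built-in and user-defined gate laws.
Folds are bisection-refined zeros of `dI_eq/dV` (|slope| < 1e−6 pA/mV at
the reported points); Hopf candidates are sign changes of the largest real
part over complex eigenvalue pairs — candidates only, no normal-form
classification.

The attractor scan integrates each grid current for 2 s from an
equilibrium-adjacent initial condition (the stable equilibrium, perturbed
by 0.1 mV; chosen from the root set of `I_eq(V) = I_h`) and from a
spike-adjacent one (V = 0 mV with hyperpolarized gate values).  A run is
"spiking" when the trailing half contains ≥3 upward crossings of −10 mV;
divergent classifications mark bistability; points whose transient cannot
be validated (fewer than 5 trailing interspike intervals, or an unsettled
rest tail) are flagged rather than silently labeled.  `I_db` is the largest
scanned current that still fires.

## Analysis pipeline

* **Smoothing**: centered moving median, 0.2 s window for the curve and
  0.75 s for the slope criterion (4×10³ and 1.5×10⁴ samples at 20 kHz).
  Edge windows shrink symmetrically and stay odd, so the median is the
  identity on monotone inputs and the mean preserves linear ramps.
* **Slope criterion**: the slope of the heavily smoothed curve is taken
  over a half-window baseline (adjacent 20 kHz samples of a 1.83 mV/s ramp
  are 0.1 µV apart — a per-sample derivative would be pure noise).  A point
  is unstable-by-slope when it lies in a contiguous negative-slope run at
  least 1 mV wide; qualifying runs separated by less than the smoothing
  window's extent in V_h (~1.4 mV) are merged, since one dropout can
  interrupt the middle branch.  Run boundaries are the fold markers.
* **Oscillation evidence**: CC firing at currents in [onset, I_db] marks
  curve points above the upper fold with matching `I_vc,sm` as unstable.
  Onset and block are the first/last *sustained* spikes — a spike with two
  more within 2 s — so isolated spikes evoked by dropout pulses in the
  merely excitable regime do not shift them.  `I_db` is the current at the
  last sustained spike (not last-spike-plus-half-ISI; configurable window).
* **Undetermined**: points above the low fold at currents the up-ramp
  passed while at rest (below firing onset) carry no evidence either way
  and are labeled undetermined.  No bifurcation marker is ever placed at an
  undetermined↔unstable boundary; fold markers are geometric turning points
  of the smoothed curve, and a Hopf marker is placed at `I_db` only when
  the mean firing amplitude of the last five cycles falls below 25 % of
  the run's maximum (amplitude collapse, the small-oscillation signature);
  otherwise the block onset is reported unclassified.
* **Slow-phase mask**: samples where |(V′Δt, V″Δt)| (smoothed finite
  differences, 1 ms window) falls below 1 % of its trace maximum.
* **τ½ fit**: per-spike voltage maxima (or trace extrema for non-spiking
  ringing) minus an asymptote taken as the mean of the last quartile,
  fitted as `A·2^(−t/τ½)` by least squares on the log₂ scale; deviations
  below 5 % of the largest are discarded as noise-dominated, and fewer
  than four usable maxima raise an error.  On a class-II subthreshold
  ringing transient the fit reproduces `−ln 2 / Re λ` of the equilibrium's
  leading eigenvalue to ~1 % (tested).
* **Bias estimates**: VC voltage lag `V̇·τ½/ln 2` (default τ½ = 75 ms)
  and CC spike-minimum bias `(dV_min/dI_h)·(dI_h/dt)·τ½/ln 2`
  (default τ½ = 200 ms, envelope slope fitted from the binned spiking
  envelope).  Both are exactly linear in each factor.
* **Drift metric**: median |I difference| between the VC curve and the CC
  rest branch on the shared stable low branch, compared at the
  reconstructed membrane voltage `V = V_h − I_vc,sm/g_c`; without the
  reconstruction the finite clamp gain itself would masquerade as drift.
* **Dropout detection**: residual (raw − median-smoothed) excursions beyond
  `k·1.4826·MAD` (k = 6), merged over 5 ms gaps because the clamp rings
  briefly after each pulse.

**Tracking-accuracy diagnostic.**  The deviation between a slow-VC run and
the equilibrium curve is measured as `|I_vc(t) − I_eq(V(t))|` at the
*recorded membrane potential*.  With a proportional clamp the hold voltage
differs from V by `I_vc/g_c` (tens of mV at high currents and moderate
gain), so comparing at `V_h` would conflate that static, gain-dependent
offset with the ramp-speed bias the diagnostic is about; at the membrane
potential the deviation is first order in the ramp speed (halving the
speed halves it — tested) and is ≈0.08 % of the traversed current range
for Morris–Lecar class I at default settings.

## Synthetic fixtures

`make_fixture` produces paired VC/CC/step recordings from one synthetic
cell.  Disturbance defaults — 5 pA·√ms white current noise, 0.5 /s dropout
pulses of 100 pA × 5 ms — are chosen at a realistic patch-clamp scale; the
experimental reference describes these artifacts qualitatively but does not
pin their magnitudes down, so they are free config parameters.  Slow drift
multiplies all maximal conductances by `1 + r·t/T` per run (leak-only drift
selectable by building a custom model); ground truth is always the
undrifted model, and the manifest (full config, seed, per-trace SHA-256)
suffices to regenerate a bundle bit-identically.  The bundled attractor
scan is seed-independent and expensive, so it is computed only on request.

What the fixtures do *not* emulate: electrode access resistance and series
resistance artifacts, amplifier filtering, capacitive transients, channel
noise, or biological trial-to-trial variability.  Passing the recovery
tests therefore shows that the pipeline is correct and robust to the
modeled disturbance structure — not that it is validated against real
recordings.

## Verified behavior (computed by the test suite)

On 20 seeded noisy class-I fixtures at default protocol and disturbance
settings, fold markers are unbiased to ≲0.1 mV / ≲0.1 pA (every individual
error < 3 mV / 5 pA), and ≥95 % of asserted stable/unstable labels agree
with the eigenvalue classification outside ±2 mV fold neighborhoods.
"Undetermined" is an abstention, not an error: the stretch between the low
fold and firing onset is genuinely unreachable by single-up-ramp evidence
(it stays < 10 % of the curve), so accuracy is scored over asserted labels
only.  The measured `I_db` of a noisy ramp exceeds the static block
current: slow passage through the subcritical region delays the firing
collapse (≈5 pA deterministically) and disturbances sustain oscillations
further (tens of pA, seed-dependent) — the same small-amplitude
oscillations above the block seen in real cells.  The class-II attractor
scan finds the firing/rest bistability window at 128–138 pA.

## Problem sizes and defaults

Default runs are full-length (60 s at 20 kHz, ~1.2 M samples); recovery
statistics use 20 seeds; attractor scans use 1–2 pA grids with 2 s windows
and two initial conditions.  Curve sampling uses 2001 points.  All defaults
are config-overridable.

## Known limitations

* Single compartment only; no spatial or multi-electrode extensions.
* Down-ramps (hysteresis protocols) are rejected by the analysis layer.
* Hopf markers are phenomenological candidates; no Lyapunov-coefficient or
  singular-Hopf classification.
* No continuation of periodic orbits — bistability comes from brute force.
* The oscillation-evidence rule associates CC firing with the curve point
  of nearest smoothed current on the upper branch; whether that evidence
  should extend below the spiking envelope's slow phase is configurable,
  not decided.
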