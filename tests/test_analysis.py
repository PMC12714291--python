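"""Trace-analysis pipeline: smoothing, labels, spikes, transients, biases, dropouts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rampclamp import (
    CCProtocol, DisturbanceConfig, Recording, VCProtocol,
    assemble_diagram, build_vc_curve, cc_bias_estimate, detect_depolarization_block,
    detect_dropouts, detect_spikes, estimate_tau_half, negative_slope_labels,
    phase_plane_embedding, simulate_cc, simulate_vc, slow_phase_mask, smooth,
    vc_as_cc_ramp_speed, vc_bias_estimate,
)
from rampclamp.errors import EstimationError, InputError

LN2 = math.log(2.0)


def make_cc(t, V, I=None):
    I = np.zeros_like(t) if I is None else I
    return Recording("CC", t, V, I, I.copy())


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmooth:
    def test_median_removes_isolated_outlier(self):
        x = np.full(50, 3.0)
        x[20] = 100.0
        assert np.allclose(smooth(x, 5, "median"), 3.0)

    def test_mean_preserves_linear_ramp_interior(self):
        x = np.linspace(0, 10, 101)
        y = smooth(x, 9, "mean")
        assert np.allclose(y[4:-4], x[4:-4])

    def test_output_length_and_edge_shrinking(self):
        x = np.arange(11.0) ** 2
        y = smooth(x, 5, "median")
        assert len(y) == len(x)
        assert y[0] == x[0]                              # symmetric edge window of 1
        assert y[1] == pytest.approx(np.median(x[:3]))   # ... of 3

    @pytest.mark.parametrize("window", [0, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(InputError):
            smooth(np.arange(10.0), window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(InputError):
            smooth(np.arange(10.0), 11)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=9, max_size=60))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_median_idempotent_on_monotone_input(self, values):
        x = np.sort(np.asarray(values))
        once = smooth(x, 5, "median")
        assert np.allclose(smooth(once, 5, "median"), once)


# ---------------------------------------------------------------------------
# measured curve and slope criterion
# ---------------------------------------------------------------------------

def toy_s_curve_recording(noise=0.01, seed=0, descending=False):
    n = 5001
    t = np.arange(n) * 0.05
    Vh = np.linspace(-2.5, 2.5, n)
    if descending:
        Vh = Vh[::-1]
    rng = np.random.default_rng(seed)
    I = Vh ** 3 - 3 * Vh + noise * rng.standard_normal(n)
    return Recording("VC", t, Vh.copy(), I, Vh.copy())


class TestVCCurve:
    def test_rejects_cc_recording(self):
        rec = make_cc(np.arange(10.0), np.zeros(10))
        with pytest.raises(InputError):
            build_vc_curve(rec)

    def test_rejects_descending_ramp(self):
        with pytest.raises(InputError):
            build_vc_curve(toy_s_curve_recording(descending=True))

    def test_middle_branch_of_toy_s_curve_labeled_unstable(self):
        curve = build_vc_curve(toy_s_curve_recording(), window=101, window_large=301)
        mask = negative_slope_labels(curve, min_run=0.2)
        inner = (curve.Vh > -0.8) & (curve.Vh < 0.8)   # well inside the fold pair
        outer = (curve.Vh < -1.2) | (curve.Vh > 1.2)
        assert mask[inner].all()
        assert not mask[outer].any()

    def test_monotone_curve_has_no_unstable_points(self):
        n = 2001
        t = np.arange(n) * 0.05
        Vh = np.linspace(-80, -40, n)
        rec = Recording("VC", t, Vh.copy(), 2.0 * (Vh + 60), Vh.copy())
        curve = build_vc_curve(rec, window=51, window_large=151)
        assert not negative_slope_labels(curve, min_run=0.5).any()


# ---------------------------------------------------------------------------
# spikes, block, slow phase, phase plane
# ---------------------------------------------------------------------------

def pulse_train_recording(times, heights=None, baseline=-60.0, width_ms=4.0,
                          dt=0.5, total=4000.0, ramp_to=None):
    t = np.arange(0.0, total, dt)
    V = np.full_like(t, baseline)
    heights = np.full(len(times), 60.0) if heights is None else heights
    for t0, h in zip(times, heights):
        tri = h * np.clip(1 - np.abs(t - t0) / (width_ms / 2), 0, None)
        V = np.maximum(V, baseline + tri)
    I = np.linspace(0.0, ramp_to, len(t)) if ramp_to else np.zeros_like(t)
    return Recording("CC", t, V, I, I.copy())


class TestSpikes:
    def test_constructed_train_recovered_exactly(self):
        times = [300.0, 500.0, 800.0, 1200.0, 1700.0, 2300.0, 3000.0]
        rec = pulse_train_recording(times)
        sp = detect_spikes(rec)
        assert len(sp.times) == 7
        # upward crossing of -10 mV occurs on the rising flank, within the pulse
        assert np.all(np.abs(sp.times - np.asarray(times)) < 2.5)

    def test_subthreshold_trace_yields_nothing(self):
        rec = make_cc(np.arange(0.0, 100.0, 0.5), -60 + 5 * np.sin(np.arange(200) / 5))
        assert len(detect_spikes(rec).times) == 0

    def test_refractory_merges_double_crossings(self):
        t = np.arange(0.0, 50.0, 0.1)
        V = np.full_like(t, -60.0)
        V[(t > 10) & (t < 10.6)] = 0.0
        V[(t > 10.8) & (t < 11.4)] = 0.0   # second crossing inside refractory
        rec = make_cc(t, V)
        assert len(detect_spikes(rec, refractory=2.0).times) == 1

    def test_block_current_from_last_spike(self):
        times = [500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0]
        rec = pulse_train_recording(times, ramp_to=400.0)
        sp = detect_spikes(rec)
        idb = detect_depolarization_block(rec, sp)
        assert idb == pytest.approx(300.0, abs=1.0)  # 3000 ms of a 0->400 pA ramp

    def test_block_absent_without_spikes(self):
        rec = make_cc(np.arange(0.0, 100.0, 0.5), np.full(200, -60.0))
        assert detect_depolarization_block(rec, detect_spikes(rec)) is None


class TestSlowPhase:
    def test_constant_trace_entirely_slow(self):
        rec = make_cc(np.arange(0.0, 100.0, 0.5), np.full(200, -55.0))
        assert slow_phase_mask(rec).all()

    def test_flagged_fraction_monotone_in_threshold(self):
        t = np.arange(0.0, 200.0, 0.1)
        rec = make_cc(t, -40 + 20 * np.sin(2 * np.pi * t / 25))
        fracs = [slow_phase_mask(rec, f).mean() for f in (0.02, 0.1, 0.3, 0.8)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_relaxation_spikes_slow_near_voltage_minimum(self, ml1):
        """During periodic firing the slow-flagged samples cluster near V_min."""
        from rampclamp import StepProtocol, simulate_step
        rec = simulate_step(ml1, StepProtocol(step_I=100.0, t_on=0.0, t_off=2000.0,
                                              total_T=2000.0))
        half = len(rec.t) // 2
        mask = slow_phase_mask(rec, 0.05)[half:]
        V = rec.V[half:]
        v_lo, v_hi = V.min(), V.max()
        assert np.median(V[mask]) < v_lo + 0.25 * (v_hi - v_lo)


class TestPhasePlane:
    def test_linear_trace_constant_velocity(self):
        t = np.arange(0.0, 10.0, 0.1)
        rec = make_cc(t, -60 + 3.0 * t)
        v, dv = phase_plane_embedding(rec)
        assert len(v) == len(t) - 1
        assert np.allclose(dv, 3.0)

    def test_sinusoid_closes_into_ellipse(self):
        t = np.arange(0.0, 100.0, 0.05)
        A, w = 10.0, 2 * np.pi / 20.0
        rec = make_cc(t, A * np.sin(w * t))
        v, dv = phase_plane_embedding(rec)
        r = (v / A) ** 2 + (dv / (A * w)) ** 2
        assert np.all(np.abs(r[:-10] - 1.0) < 0.05)


# ---------------------------------------------------------------------------
# transient fit and bias estimates
# ---------------------------------------------------------------------------

def decaying_train(tau=200.0, A=15.0, peak_noise=0.0, seed=0):
    times = np.arange(100.0, 3900.0, 50.0)
    rng = np.random.default_rng(seed)
    heights = 55.0 + A * 2.0 ** (-times / tau) + peak_noise * rng.standard_normal(len(times))
    return pulse_train_recording(times, heights)


class TestTauHalf:
    def test_exact_constructed_decay_recovered(self):
        rec = decaying_train(tau=200.0)
        sp = detect_spikes(rec)
        fit = estimate_tau_half(rec, sp)
        assert fit.tau_half == pytest.approx(200.0, rel=1e-3)
        assert fit.asymptote == pytest.approx(-5.0, abs=0.01)

    def test_noisy_maxima_recovered_within_five_percent(self):
        errs = []
        for seed in range(10):
            rec = decaying_train(tau=200.0, peak_noise=0.1, seed=seed)
            fit = estimate_tau_half(rec, detect_spikes(rec))
            errs.append(abs(fit.tau_half - 200.0) / 200.0)
        assert np.mean(errs) < 0.05
        assert max(errs) < 0.10

    def test_too_few_maxima_rejected(self):
        rec = pulse_train_recording([500.0, 1500.0], heights=[70.0, 65.0])
        with pytest.raises(EstimationError):
            estimate_tau_half(rec, detect_spikes(rec))

    def test_ringing_decay_matches_eigenvalue_rate(self, ml2):
        """Subthreshold ringing below the Hopf decays at -ln2/Re(lambda); the
        extrema-based fit must recover that rate (independent linear oracle)."""
        from scipy.optimize import brentq

        from rampclamp import StepProtocol, simulate_step, stability_eigenvalues

        I_step = 125.0
        rec = simulate_step(ml2, StepProtocol(0.0, I_step, 100.0, 4100.0, 4200.0))
        on = (rec.t >= 150.0) & (rec.t < 4100.0)
        window = Recording("CC", rec.t[on] - 150.0, rec.V[on], rec.I[on],
                           rec.command[on])
        fit = estimate_tau_half(window)
        v_eq = brentq(lambda v: float(ml2.equilibrium_current(v)) - I_step, -60.0, 20.0)
        lam = stability_eigenvalues(ml2, v_eq, "CC").real.max()
        assert fit.tau_half == pytest.approx(-LN2 / lam, rel=0.1)

    def test_flat_maxima_rejected(self):
        """Already-settled spiking has no usable decaying deviations to fit."""
        times = np.arange(100.0, 2000.0, 50.0)
        rec = pulse_train_recording(times, np.full(len(times), 60.0))
        with pytest.raises(EstimationError):
            estimate_tau_half(rec, detect_spikes(rec))


class TestBiasEstimates:
    def test_vc_bound_reproduced(self):
        # 1.83 mV/s ramp, 75 ms recovery half-time
        v = vc_bias_estimate(1.83e-3, 75.0)
        assert v == pytest.approx(1.83e-3 * 75.0 / LN2, rel=1e-15)
        assert v <= 0.2

    def test_vc_zero_speed_gives_zero(self):
        assert vc_bias_estimate(0.0, 75.0) == 0.0

    def test_vc_current_bias_uses_local_slope(self):
        est = vc_bias_estimate(1.83e-3, 75.0, dIeq_dV=20.0)
        assert est.current_pA == pytest.approx(est.voltage_mV * 20.0, rel=1e-15)

    def test_cc_worked_example(self):
        # envelope slope 8 mV / 120 pA, ramp 7.5 pA/s, tau_half 0.2 s
        assert cc_bias_estimate(8.0 / 120.0, 7.5e-3, 200.0) == \
            pytest.approx((8.0 / 120.0) * 7.5e-3 * 200.0 / LN2, rel=1e-15)

    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3), st.floats(0.5, 4.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_linearity_in_each_argument(self, a, b, k):
        assert vc_bias_estimate(k * a, b) == pytest.approx(k * vc_bias_estimate(a, b), rel=1e-12)
        assert cc_bias_estimate(a, k * b, 100.0) == \
            pytest.approx(k * cc_bias_estimate(a, b, 100.0), rel=1e-12)

    def test_recast_ramp_speed_product(self):
        assert vc_as_cc_ramp_speed(20.0, 0.183) == pytest.approx(3.66, rel=1e-12)


# ---------------------------------------------------------------------------
# dropouts
# ---------------------------------------------------------------------------

class TestDropouts:
    def _curve(self, pulses=(), amp=-60.0, seed=0):
        n = 20001
        t = np.arange(n) * 0.05
        Vh = np.linspace(-80.0, -60.0, n)
        rng = np.random.default_rng(seed)
        I = 2.0 * (Vh + 60.0) + 0.5 * rng.standard_normal(n)
        for t0 in pulses:
            sel = (t >= t0) & (t < t0 + 5.0)
            I[sel] += amp
        rec = Recording("VC", t, Vh.copy(), I, Vh.copy())
        return build_vc_curve(rec, window=401, window_large=801)

    def test_clean_curve_has_no_events(self):
        assert detect_dropouts(self._curve()) == []

    def test_five_injected_pulses_recovered(self):
        pulses = (100.0, 300.0, 450.0, 700.0, 900.0)
        events = detect_dropouts(self._curve(pulses=pulses))
        assert len(events) == 5
        for ev, t0 in zip(events, pulses):
            assert abs(ev.onset_ms - t0) < 1.0
            assert ev.peak_pA < -30.0

    def test_event_count_monotone_in_threshold(self):
        curve = self._curve(pulses=(100.0, 300.0, 450.0), amp=-20.0, seed=5)
        counts = [len(detect_dropouts(curve, k)) for k in (3.0, 6.0, 12.0, 40.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# diagram assembly
# ---------------------------------------------------------------------------

class TestAssembleDiagram:
    def test_leak_pair_all_stable_no_markers(self, leak):
        vc = simulate_vc(leak, VCProtocol(Vh_start=-80, Vh_end=-10, ramp_speed=1.83e-3,
                                          gc=40.0), DisturbanceConfig(seed=1))
        cc = simulate_cc(leak, CCProtocol(Ih_start=-40.0, Ih_end=100.0, ramp_speed=7e-3),
                         DisturbanceConfig(seed=2))
        diag = assemble_diagram(build_vc_curve(vc), cc)
        assert (diag.labeling.label == "stable").all()
        assert diag.labeling.folds == [] and diag.labeling.hopf == []
        assert diag.I_db is None
        assert diag.drift_metric < 1.0  # pA; same cell, no drift

    def test_class_i_pair_recovers_structure(self, ml1_diagram, ml1_curve):
        diag = ml1_diagram
        lab = diag.labeling
        assert len(lab.folds) >= 2
        truth = [(v + i / ml1_curve.gc, i) for v, i in ml1_curve.folds]
        for (vt, it) in truth:
            vm, im = min(lab.folds, key=lambda f: abs(f[0] - vt))
            assert abs(vm - vt) < 2.0
            assert abs(im - it) < 5.0
        assert (lab.basis == "slope").any()
        assert (lab.basis == "oscillation-evidence").any()
        assert diag.onset_I == pytest.approx(ml1_curve.folds[0][1], abs=5.0)
        assert diag.I_db is not None and diag.I_db > ml1_curve.hopf[0][1] - 10.0

    def test_cc_started_above_fold_leaves_undetermined_gap(self, ml1, ml1_noisy_pair):
        vc, _ = ml1_noisy_pair
        cc = simulate_cc(ml1, CCProtocol(Ih_start=80.0, Ih_end=280.0),
                         DisturbanceConfig(noise_sd=5.0, dropout_rate=0.5,
                                           dropout_amplitude=100.0,
                                           dropout_duration=5.0, seed=77))
        diag = assemble_diagram(build_vc_curve(vc), cc)
        lab = diag.labeling
        undet = lab.label == "undetermined"
        assert undet.any()
        # the gap sits at currents the up-ramp never probed while at rest
        assert diag.curve.I_sm[undet].max() <= diag.onset_I + 1.0
        # and no Hopf marker is placed at an undetermined boundary
        for _, i in lab.hopf:
            assert i == pytest.approx(diag.I_db, abs=1.0)

    def test_rejects_vc_overlay(self, ml1_noisy_pair):
        vc, _ = ml1_noisy_pair
        curve = build_vc_curve(vc)
        with pytest.raises(InputError):
            assemble_diagram(curve, vc)

    def test_bias_estimates_populated(self, ml1_diagram):
        assert ml1_diagram.bias_vc_mV == pytest.approx(1.83e-3 * 75.0 / LN2, rel=1e-12)
        assert np.isfinite(ml1_diagram.bias_cc_mV)
        assert np.isfinite(ml1_diagram.dVmin_dI)

    def test_json_and_table_round_out(self, ml1_diagram):
        js = ml1_diagram.to_json()
        assert {"segments", "folds", "I_db_pA", "drift_metric_pA"} <= set(js)
        table = ml1_diagram.to_table()
        assert set(table.columns) == {"Vh_mV", "I_sm_pA", "label", "basis"}
        assert len(table) == len(ml1_diagram.curve.Vh)
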