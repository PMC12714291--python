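"""Slow-ramp voltage-clamp / current-clamp / step protocol simulation.

The voltage-clamp (VC) protocol is a closed loop: a proportional controller
with gain ``gc`` injects ``I_ext = gc (Vh - V)`` to pull the membrane toward
a hold voltage ``Vh`` that ramps linearly at the slow speed ``eps * DeltaV``
(default 1.83 mV/s, i.e. eps = 0.01 of the fast voltage scale 0.183 mV/ms);
the measured quantity is the feedback current ``Ivc = gc (Vh - V)``.  The
current-clamp (CC) protocol is open loop: a hold current ``Ih`` ramps slowly
(default ~7 pA/s) and the free membrane potential is measured.  Step
protocols inject a piecewise-constant current, used for transient
(half-decay-time) calibration.

Deterministic runs use scipy's adaptive stiff solver (LSODA, rtol 1e-8 /
atol 1e-10) sampled on a uniform grid (default 0.05 ms, i.e. 20 kHz).  When
a :class:`DisturbanceConfig` is given, integration switches to a fixed-step
Euler-Maruyama scheme at the sampling interval (optionally subdivided) with
additive current noise of per-step standard deviation ``noise_sd/sqrt(dt)``
plus Poisson-timed square "dropout" current pulses; disturbances enter the
membrane equation, while the recorded VC current is the clean feedback term,
so dropout artifacts reach the recording through the voltage, as they do in
a real clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import _stepper
from .errors import InputError, SimulationError
from .models import (
    LAW_TANH, LAW_TANH_SECH, LAW_WB_M, LAW_WB_H, LAW_WB_N, Model,
)

__all__ = [
    "VCProtocol",
    "CCProtocol",
    "StepProtocol",
    "DisturbanceConfig",
    "Recording",
    "simulate_vc",
    "simulate_cc",
    "simulate_step",
    "simulate_cc_schedule",
    "relax",
]

#: default sampling interval, ms (20 kHz)
DEFAULT_SAMPLE_DT = 0.05
#: settling time before the recorded window, ms
RELAX_T = 500.0


@dataclass(frozen=True)
class VCProtocol:
    """Slow voltage ramp under feedback clamp; speeds in mV/ms."""

    Vh_start: float = -80.0
    Vh_end: float = 30.0
    ramp_speed: float = 1.83e-3  # mV/ms (eps * DeltaV with eps = 0.01)
    gc: Optional[float] = None   # nS; None -> model default
    sample_dt: float = DEFAULT_SAMPLE_DT

    def __post_init__(self):
        if self.ramp_speed == 0:
            raise InputError("VC ramp_speed must be nonzero")
        if self.gc is not None and self.gc <= 0:
            raise InputError("gc must be > 0")
        if self.sample_dt <= 0:
            raise InputError("sample_dt must be > 0")
        if (self.Vh_end - self.Vh_start) * self.ramp_speed < 0:
            raise InputError("ramp_speed sign must match Vh_end - Vh_start")


@dataclass(frozen=True)
class CCProtocol:
    """Slow current ramp, open loop; speeds in pA/ms."""

    Ih_start: float = 0.0
    Ih_end: float = 420.0
    ramp_speed: float = 7.0e-3  # pA/ms (~7 pA/s)
    sample_dt: float = DEFAULT_SAMPLE_DT

    def __post_init__(self):
        if self.ramp_speed == 0 and self.Ih_end != self.Ih_start:
            raise InputError("CC ramp_speed must be nonzero for a nontrivial ramp")
        if self.sample_dt <= 0:
            raise InputError("sample_dt must be > 0")
        if (self.Ih_end - self.Ih_start) * self.ramp_speed < 0:
            raise InputError("ramp_speed sign must match Ih_end - Ih_start")


@dataclass(frozen=True)
class StepProtocol:
    """Piecewise-constant current: baseline, step between t_on and t_off; times in ms."""

    baseline_I: float = 0.0
    step_I: float = 200.0
    t_on: float = 100.0
    t_off: float = 1600.0
    total_T: float = 2000.0
    sample_dt: float = DEFAULT_SAMPLE_DT

    def __post_init__(self):
        if not (0 <= self.t_on < self.t_off <= self.total_T):
            raise InputError("require 0 <= t_on < t_off <= total_T")
        if self.sample_dt <= 0:
            raise InputError("sample_dt must be > 0")


@dataclass(frozen=True)
class DisturbanceConfig:
    """Additive current disturbances: white noise plus Poisson dropout pulses.

    ``noise_sd`` is in pA*sqrt(ms) (per-step current sd is noise_sd/sqrt(dt));
    dropout events occur at ``dropout_rate`` per second, each a square pulse
    of ``dropout_amplitude`` pA lasting ``dropout_duration`` ms.
    """

    noise_sd: float = 0.0
    dropout_rate: float = 0.0       # events/s
    dropout_amplitude: float = 0.0  # pA
    dropout_duration: float = 0.0   # ms
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("noise_sd", "dropout_rate", "dropout_amplitude", "dropout_duration"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.active and self.seed is None:
            raise InputError("seed is mandatory when any disturbance magnitude is > 0")

    @property
    def active(self) -> bool:
        return self.noise_sd > 0 or (
            self.dropout_rate > 0 and self.dropout_amplitude != 0 and self.dropout_duration > 0
        )


@dataclass
class Recording:
    """A uniformly sampled clamp recording.

    ``V`` is the membrane potential trace (mV); ``I`` the measured/applied
    current (VC: feedback current Ivc; CC: applied Ih), ``command`` the
    commanded variable (VC: Vh; CC/step: Ih).
    """

    mode: str                 # "VC" or "CC"
    t: np.ndarray             # ms, uniform
    V: np.ndarray             # mV
    I: np.ndarray             # pA
    command: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("VC", "CC"):
            raise InputError(f"mode must be 'VC' or 'CC', got {self.mode!r}")
        n = len(self.t)
        if not (len(self.V) == len(self.I) == len(self.command) == n):
            raise InputError("t, V, I, command must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InputError("time grid must be strictly increasing and uniform")

    @property
    def sample_dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else float("nan")


# ---------------------------------------------------------------------------
# right-hand-side closures (fast scalar evaluation for the adaptive solver)
# ---------------------------------------------------------------------------

def _scalar_gate_funcs(law: int, p0: float, p1: float):
    if law in (LAW_TANH, LAW_TANH_SECH):
        def xinf(V, p0=p0, p1=p1):
            return 0.5 * (1.0 + math.tanh((V - p0) / p1))
        if law == LAW_TANH:
            tau = lambda V: 1.0
        else:
            def tau(V, p0=p0, p1=p1):
                return 1.0 / math.cosh((V - p0) / (2.0 * p1))
        return xinf, tau

    def _lin(u, s):
        su = s * u
        if abs(su) < 1e-8:
            return 1.0 / s + u / 2.0
        return u / (-math.expm1(-su))

    if law == LAW_WB_M:
        ab = lambda V: (0.1 * _lin(V + 35.0, 0.1), 4.0 * math.exp(-0.0556 * (V + 60.0)))
    elif law == LAW_WB_H:
        ab = lambda V: (0.07 * math.exp(-0.05 * (V + 58.0)),
                        1.0 / (1.0 + math.exp(-0.1 * (V + 28.0))))
    elif law == LAW_WB_N:
        ab = lambda V: (0.01 * _lin(V + 34.0, 0.1), 0.125 * math.exp(-0.0125 * (V + 44.0)))
    else:  # pragma: no cover
        raise InputError(f"unknown law {law}")

    def xinf(V, ab=ab):
        a, b = ab(V)
        return a / (a + b)

    def tau(V, ab=ab):
        a, b = ab(V)
        return 1.0 / (a + b)

    return xinf, tau


def _make_rhs(model: Model, i_ext_fn: Callable[[float, float], float],
              drift_slope: float = 0.0):
    """Build f(t, y) for the adaptive solver.

    ``i_ext_fn(t, V)`` returns the external current; ``drift_slope`` scales
    all maximal conductances as (1 + drift_slope * t).
    """
    C = model.capacitance
    terms = []  # (g_max, E_rev, [(xinf, tau, exponent, phi, dyn_slot)])
    slot = 0
    for cur in model.currents:
        gates = []
        for gate in cur.gates:
            xinf, tau = _scalar_gate_funcs(gate.law, *(gate.params + (0.0, 1.0))[:2])
            ds = slot if gate.dynamic else -1
            if gate.dynamic:
                slot += 1
            gates.append((xinf, tau, gate.exponent, gate.rate_scale, ds))
        terms.append((cur.g_max, cur.E_rev, gates))

    n_dyn = slot

    def f(t, y):
        V = y[0]
        gscale = 1.0 + drift_slope * t
        i_ion = 0.0
        dy = np.empty(1 + n_dyn)
        for g_max, e_rev, gates in terms:
            act = 1.0
            for xinf, tau, expo, phi, ds in gates:
                x = y[1 + ds] if ds >= 0 else xinf(V)
                act *= x ** expo
                if ds >= 0:
                    dy[1 + ds] = phi * (xinf(V) - x) / tau(V)
            i_ion += gscale * g_max * act * (V - e_rev)
        dy[0] = (-i_ion + i_ext_fn(t, V)) / C
        return dy

    return f


def _solve(model, i_ext_fn, y0, t_eval, drift_slope=0.0, rtol=1e-8, atol=1e-10):
    f = _make_rhs(model, i_ext_fn, drift_slope)
    sol = solve_ivp(f, (t_eval[0], t_eval[-1]), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t_eval[0]
        raise SimulationError(f"integrator failed near t = {t_fail:.3f} ms: {sol.message}")
    return sol.y


def relax(model: Model, i_ext_fn, V0: float, T: float = RELAX_T) -> np.ndarray:
    """Integrate for ``T`` ms from (V0, x_inf(V0)) and return the final state."""
    y0 = np.concatenate([[V0], model.dynamic_gate_steady_state(V0)])
    f = _make_rhs(model, i_ext_fn)
    sol = solve_ivp(f, (0.0, T), y0, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise SimulationError(f"relaxation failed: {sol.message}")
    return sol.y[:, -1]


# ---------------------------------------------------------------------------
# disturbance realization
# ---------------------------------------------------------------------------

def _disturbance_array(dist: DisturbanceConfig, n_sub: int, dt_sub: float):
    """Realize the disturbance current on the substep grid (deterministic per seed).

    Returns the per-substep current and the realized dropout onset times (ms).
    """
    rng = np.random.default_rng(dist.seed)
    out = np.zeros(n_sub)
    onsets = np.empty(0)
    if dist.noise_sd > 0:
        out += rng.standard_normal(n_sub) * (dist.noise_sd / math.sqrt(dt_sub))
    if dist.dropout_rate > 0 and dist.dropout_amplitude != 0 and dist.dropout_duration > 0:
        total_s = n_sub * dt_sub / 1000.0
        n_ev = rng.poisson(dist.dropout_rate * total_s)
        onsets = np.sort(rng.uniform(0.0, n_sub * dt_sub, size=n_ev))
        w = max(1, int(round(dist.dropout_duration / dt_sub)))
        for t0 in onsets:
            i0 = int(t0 / dt_sub)
            out[i0:i0 + w] += dist.dropout_amplitude
    return out, onsets


# ---------------------------------------------------------------------------
# protocol simulations
# ---------------------------------------------------------------------------

def _euler_run(model, y0, n_out, substeps, sample_dt, mode_vc, cmd0, cmd_rate,
               gc, dist, drift_slope):
    p = model.pack()
    if dist is not None:
        d, onsets = _disturbance_array(dist, (n_out - 1) * substeps, sample_dt / substeps)
    else:
        d, onsets = np.zeros((n_out - 1) * substeps), np.empty(0)
    V = np.empty(n_out)
    cmd = np.empty(n_out)
    _stepper.run_euler(p["C"], p["gmax"], p["erev"], p["law"], p["p0"], p["p1"],
                       p["expo"], p["cur_idx"], p["dyn_slot"], p["phi"],
                       np.asarray(y0, float), n_out, substeps, sample_dt,
                       mode_vc, cmd0, cmd_rate, gc, d, drift_slope, V, cmd)
    if not np.all(np.isfinite(V)):
        bad = int(np.argmax(~np.isfinite(V)))
        raise SimulationError(f"fixed-step integration diverged near t = {bad * sample_dt:.3f} ms")
    return V, cmd, onsets


def _meta(model, prot, dist, drift, extra=None):
    md = {
        "model": model.name,
        "protocol": asdict(prot),
        "disturbance": asdict(dist) if dist is not None else None,
        "relative_drift": drift,
        "seed": dist.seed if dist is not None else None,
        "sample_dt": prot.sample_dt,
    }
    if extra:
        md.update(extra)
    return md


def simulate_vc(model: Model, prot: VCProtocol = VCProtocol(),
                dist: Optional[DisturbanceConfig] = None,
                relative_drift: float = 0.0, substeps: int = 1) -> Recording:
    """Simulate the slow-ramp voltage-clamp protocol.

    The initial state is found by relaxing for 500 ms at the starting hold
    voltage; the recorded current is the clean feedback term gc*(Vh - V).
    ``relative_drift`` scales all maximal conductances linearly in time by
    that relative amount over the full ramp.
    """
    gc = prot.gc if prot.gc is not None else model.gc_default
    duration = (prot.Vh_end - prot.Vh_start) / prot.ramp_speed
    n_out = int(round(duration / prot.sample_dt)) + 1
    t = np.arange(n_out) * prot.sample_dt
    drift_slope = relative_drift / duration if duration > 0 else 0.0

    y0 = relax(model, lambda _t, V: gc * (prot.Vh_start - V), prot.Vh_start)

    extra = {"gc": gc}
    if dist is not None:
        V, cmd, onsets = _euler_run(model, y0, n_out, substeps, prot.sample_dt, True,
                                    prot.Vh_start, prot.ramp_speed, gc, dist, drift_slope)
        extra["dropout_onsets_ms"] = onsets.tolist()
    else:
        cmd = prot.Vh_start + prot.ramp_speed * t
        y = _solve(model, lambda _t, V: gc * (prot.Vh_start + prot.ramp_speed * _t - V),
                   y0, t, drift_slope)
        V = y[0]

    return Recording("VC", t, V, gc * (cmd - V), cmd,
                     _meta(model, prot, dist, relative_drift, extra))


def simulate_cc(model: Model, prot: CCProtocol = CCProtocol(),
                dist: Optional[DisturbanceConfig] = None,
                relative_drift: float = 0.0, substeps: int = 1) -> Recording:
    """Simulate the slow-ramp current-clamp protocol (open loop).

    The initial state is relaxed for 500 ms at the starting hold current from
    the lowest-voltage equilibrium of the undisturbed model.
    """
    if prot.Ih_end == prot.Ih_start:
        duration = 1000.0  # zero-length ramp: 1 s constant-current run
        rate = 0.0
    else:
        duration = (prot.Ih_end - prot.Ih_start) / prot.ramp_speed
        rate = prot.ramp_speed
    n_out = int(round(duration / prot.sample_dt)) + 1
    t = np.arange(n_out) * prot.sample_dt
    drift_slope = relative_drift / duration if duration > 0 else 0.0

    V0 = _rest_voltage_guess(model, prot.Ih_start)
    y0 = relax(model, lambda _t, _V: prot.Ih_start, V0)

    extra = {}
    if dist is not None:
        V, cmd, onsets = _euler_run(model, y0, n_out, substeps, prot.sample_dt, False,
                                    prot.Ih_start, rate, 0.0, dist, drift_slope)
        extra["dropout_onsets_ms"] = onsets.tolist()
    else:
        cmd = prot.Ih_start + rate * t
        y = _solve(model, lambda _t, _V: prot.Ih_start + rate * _t, y0, t, drift_slope)
        V = y[0]

    return Recording("CC", t, V, cmd.copy(), cmd,
                     _meta(model, prot, dist, relative_drift, extra))


def simulate_step(model: Model, prot: StepProtocol = StepProtocol()) -> Recording:
    """Simulate a step-current protocol (deterministic, no disturbances)."""
    n_out = int(round(prot.total_T / prot.sample_dt)) + 1
    t = np.arange(n_out) * prot.sample_dt
    cmd = np.where((t >= prot.t_on) & (t < prot.t_off), prot.step_I, prot.baseline_I)

    V0 = _rest_voltage_guess(model, prot.baseline_I)
    y0 = relax(model, lambda _t, _V: prot.baseline_I, V0)

    # integrate segment-wise so the solver never straddles a discontinuity
    edges = [0.0, prot.t_on, prot.t_off, prot.total_T]
    V = np.empty(n_out)
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        sel = (t >= a) & (t <= b)
        tt = t[sel]
        if len(tt) == 0 or tt[0] > a:
            tt = np.concatenate([[a], tt])
            pad = True
        else:
            pad = False
        i_val = prot.step_I if (prot.t_on <= a < prot.t_off) else prot.baseline_I
        yy = _solve(model, lambda _t, _V, i_val=i_val: i_val, y, tt)
        V[sel] = yy[0, 1:] if pad else yy[0]
        y = yy[:, -1]

    return Recording("CC", t, V, cmd.astype(float), cmd.astype(float),
                     _meta(model, prot, None, 0.0))


def simulate_cc_schedule(model: Model, t: np.ndarray, I: np.ndarray,
                         y0: Optional[np.ndarray] = None) -> Recording:
    """Current-clamp run with an arbitrary current schedule I(t) (linear interp).

    Used by the recasting diagnostic, which feeds a smoothed VC current back
    into the model as a CC drive.
    """
    t = np.asarray(t, float)
    I = np.asarray(I, float)
    if len(t) != len(I):
        raise InputError("t and I must have equal length")
    if y0 is None:
        V0 = _rest_voltage_guess(model, I[0])
        y0 = relax(model, lambda _t, _V: I[0], V0)

    def i_fn(tt, _V):
        return np.interp(tt, t, I)

    y = _solve(model, i_fn, y0, t)
    return Recording("CC", t - t[0], y[0], I.copy(), I.copy(),
                     {"model": model.name, "protocol": "cc_schedule",
                      "sample_dt": float(t[1] - t[0]) if len(t) > 1 else None})


def _rest_voltage_guess(model: Model, Ih: float) -> float:
    """Lowest-voltage solution of I_eq(V) = Ih (rest-branch guess)."""
    Vg = np.linspace(-100.0, 40.0, 561)
    r = model.equilibrium_current(Vg) - Ih
    sign = np.sign(r)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return -65.0
    i = idx[0]
    # linear interpolation of the first sign change
    v0, v1 = Vg[i], Vg[i + 1]
    r0, r1 = r[i], r[i + 1]
    return float(v0 - r0 * (v1 - v0) / (r1 - r0))
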