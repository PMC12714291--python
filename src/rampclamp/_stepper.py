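"""Compiled fixed-step Euler-Maruyama integrator for noisy protocol runs.

The deterministic simulations use scipy's adaptive stiff solver; runs with
additive current noise and dropout pulses use this fixed-step kernel at the
sampling interval (optionally subdivided), which keeps minute-long 20 kHz
simulations fast and reproducible.  The model is passed as flat parameter
arrays produced by :meth:`rampclamp.models.Model.pack`; the disturbance
current is precomputed on the substep grid outside the kernel, so the kernel
itself is deterministic.
"""

import numpy as np
from numba import njit

# gate-law ids, mirroring rampclamp.models
_LAW_TANH = 0
_LAW_TANH_SECH = 1
_LAW_WB_M = 2
_LAW_WB_H = 3
_LAW_WB_N = 4


@njit(cache=True)
def _lin_over_expm1(u, s):
    su = s * u
    if abs(su) < 1e-8:
        return 1.0 / s + u / 2.0
    return u / (-np.expm1(-su))


@njit(cache=True)
def _gate_inf(law, p0, p1, V):
    if law == _LAW_TANH or law == _LAW_TANH_SECH:
        return 0.5 * (1.0 + np.tanh((V - p0) / p1))
    if law == _LAW_WB_M:
        a = 0.1 * _lin_over_expm1(V + 35.0, 0.1)
        b = 4.0 * np.exp(-0.0556 * (V + 60.0))
        return a / (a + b)
    if law == _LAW_WB_H:
        a = 0.07 * np.exp(-0.05 * (V + 58.0))
        b = 1.0 / (1.0 + np.exp(-0.1 * (V + 28.0)))
        return a / (a + b)
    # _LAW_WB_N
    a = 0.01 * _lin_over_expm1(V + 34.0, 0.1)
    b = 0.125 * np.exp(-0.0125 * (V + 44.0))
    return a / (a + b)


@njit(cache=True)
def _gate_tau(law, p0, p1, V):
    if law == _LAW_TANH:
        return 1.0
    if law == _LAW_TANH_SECH:
        return 1.0 / np.cosh((V - p0) / (2.0 * p1))
    if law == _LAW_WB_M:
        a = 0.1 * _lin_over_expm1(V + 35.0, 0.1)
        b = 4.0 * np.exp(-0.0556 * (V + 60.0))
        return 1.0 / (a + b)
    if law == _LAW_WB_H:
        a = 0.07 * np.exp(-0.05 * (V + 58.0))
        b = 1.0 / (1.0 + np.exp(-0.1 * (V + 28.0)))
        return 1.0 / (a + b)
    a = 0.01 * _lin_over_expm1(V + 34.0, 0.1)
    b = 0.125 * np.exp(-0.0125 * (V + 44.0))
    return 1.0 / (a + b)


@njit(cache=True)
def run_euler(C, gmax, erev, law, p0, p1, expo, cur_idx, dyn_slot, phi,
              y0, n_out, substeps, sample_dt,
              mode_vc, cmd0, cmd_rate, gc,
              dist, drift_slope,
              V_out, cmd_out):
    """Integrate a ramped clamp protocol with additive disturbance current.

    The commanded variable is cmd(t) = cmd0 + cmd_rate * t: the hold voltage
    Vh for mode_vc=True (I_ext = gc*(cmd - V) + dist) or the hold current Ih
    otherwise (I_ext = cmd + dist).  ``dist`` has length (n_out-1)*substeps
    and holds the disturbance current per substep.  ``drift_slope`` scales all
    maximal conductances as (1 + drift_slope * t).  V and cmd are recorded on
    the sample grid into V_out/cmd_out (length n_out).
    """
    n_cur = gmax.shape[0]
    n_g = law.shape[0]
    dt = sample_dt / substeps
    y = y0.copy()
    act = np.empty(n_cur)
    idx = 0
    for k in range(n_out):
        tk = k * sample_dt
        V_out[k] = y[0]
        cmd_out[k] = cmd0 + cmd_rate * tk
        if k == n_out - 1:
            break
        for s in range(substeps):
            t = tk + s * dt
            V = y[0]
            gscale = 1.0 + drift_slope * t
            for c in range(n_cur):
                act[c] = 1.0
            for g in range(n_g):
                if dyn_slot[g] >= 0:
                    x = y[1 + dyn_slot[g]]
                else:
                    x = _gate_inf(law[g], p0[g], p1[g], V)
                xe = x
                for _ in range(expo[g] - 1):
                    xe *= x
                act[cur_idx[g]] *= xe
            i_ion = 0.0
            for c in range(n_cur):
                i_ion += gscale * gmax[c] * act[c] * (V - erev[c])
            cmd_t = cmd0 + cmd_rate * t
            if mode_vc:
                i_ext = gc * (cmd_t - V)
            else:
                i_ext = cmd_t
            i_ext += dist[idx]
            idx += 1
            y[0] = V + dt * (-i_ion + i_ext) / C
            for g in range(n_g):
                sl = dyn_slot[g]
                if sl >= 0:
                    xinf = _gate_inf(law[g], p0[g], p1[g], V)
                    tau = _gate_tau(law[g], p0[g], p1[g], V)
                    y[1 + sl] += dt * phi[g] * (xinf - y[1 + sl]) / tau
    return y
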