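"""Analytic/numerical ground truth for conductance-based models.

The steady-state I-V curve I_eq(V) (all gates at steady state) is the
steady-state bifurcation diagram of the model's fast subsystem: under
current clamp its equilibria satisfy I_eq(V) = Ih, under voltage clamp
I_eq(V) = gc (Vh - V).  Both describe the same set of points in the (I, V)
plane, so the curve is sampled on a uniform voltage grid (I_eq is
single-valued in V; branches that are multivalued in I need no
continuation).  Each point carries the eigenvalues of the fast-subsystem
Jacobian under current clamp and under voltage clamp at gain gc; folds are
zeros of dI_eq/dV and Hopf candidates are zero crossings of the real part
of a complex eigenvalue pair (no normal-form classification).

Jacobians are computed by central finite differences of the right-hand side
(step scaled to the state magnitude), which keeps user-defined gate laws on
the same code path as the built-ins.

:func:`attractor_scan` classifies the long-run behavior under constant
current by brute-force integration from an equilibrium-adjacent and a
spike-adjacent initial condition, reporting spiking envelopes, interspike
intervals, bistable intervals, and the depolarization-block current I_db
(the largest scanned current that still supports firing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .errors import InputError, SimulationError
from .models import Model
from .protocols import _make_rhs

__all__ = [
    "SteadyStatePoint",
    "SteadyStateCurve",
    "AttractorScan",
    "steady_state_curve",
    "stability_eigenvalues",
    "find_folds",
    "find_hopf",
    "attractor_scan",
]

SPIKE_THRESHOLD = -10.0  # mV, upward-crossing threshold for spike counting


# ---------------------------------------------------------------------------
# Jacobians and eigenvalues
# ---------------------------------------------------------------------------

def _jacobian(model: Model, V: float, mode: str, gc: Optional[float] = None,
              h: float = 1e-6) -> np.ndarray:
    """Central-FD Jacobian of the fast subsystem at the equilibrium (V, x_inf(V)).

    mode "CC": I_ext held constant.  mode "VC": I_ext = gc*(Vh - V) with Vh
    fixed at the consistent value, which only adds -gc/C to d(dV/dt)/dV.
    """
    y = np.concatenate([[V], model.dynamic_gate_steady_state(V)])
    n = len(y)
    ieq = float(model.equilibrium_current(V))
    J = np.empty((n, n))
    for j in range(n):
        step = h * (1.0 + abs(y[j]))
        yp = y.copy(); yp[j] += step
        ym = y.copy(); ym[j] -= step
        J[:, j] = (model.rhs(yp, ieq) - model.rhs(ym, ieq)) / (2 * step)
    if mode == "VC":
        if gc is None:
            raise InputError("VC mode requires gc")
        J[0, 0] -= gc / model.capacitance
    elif mode != "CC":
        raise InputError(f"mode must be 'CC' or 'VC', got {mode!r}")
    return J


def stability_eigenvalues(model: Model, V: float, mode: str = "CC",
                          gc: Optional[float] = None) -> np.ndarray:
    """Eigenvalues (1/ms) of the fast-subsystem Jacobian at the equilibrium for V."""
    return np.linalg.eigvals(_jacobian(model, V, mode, gc))


# ---------------------------------------------------------------------------
# Steady-state curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyStatePoint:
    V: float
    I_eq: float
    gates: dict
    eig_cc: np.ndarray
    eig_vc: np.ndarray
    stable_cc: bool
    stable_vc: bool


@dataclass
class SteadyStateCurve:
    """Sampled steady-state I-V curve with per-point stability information.

    ``Vh`` is the hold voltage at which the voltage-clamp fast subsystem has
    its equilibrium at V (Vh = V + I_eq(V)/gc), so (I_eq, Vh) is the curve
    the clamp traces in the measured coordinates.
    """

    V: np.ndarray
    I_eq: np.ndarray
    Vh: np.ndarray
    gates: dict
    eig_cc: np.ndarray       # (n, dim) complex
    eig_vc: np.ndarray
    stable_cc: np.ndarray    # bool
    stable_vc: np.ndarray
    gc: float
    folds: list = field(default_factory=list)   # [(V, I), ...]
    hopf: list = field(default_factory=list)
    model: Optional[Model] = None

    def point(self, i: int) -> SteadyStatePoint:
        return SteadyStatePoint(
            V=float(self.V[i]), I_eq=float(self.I_eq[i]),
            gates={k: float(v[i]) for k, v in self.gates.items()},
            eig_cc=self.eig_cc[i], eig_vc=self.eig_vc[i],
            stable_cc=bool(self.stable_cc[i]), stable_vc=bool(self.stable_vc[i]),
        )

    def dI_dV(self) -> np.ndarray:
        return np.gradient(self.I_eq, self.V)

    def to_table(self):
        import pandas as pd
        d = {"V_mV": self.V, "I_eq_pA": self.I_eq, "Vh_mV": self.Vh,
             "stable_cc": self.stable_cc, "stable_vc": self.stable_vc,
             "max_re_eig_cc": self.eig_cc.real.max(axis=1),
             "max_re_eig_vc": self.eig_vc.real.max(axis=1)}
        for k, v in self.gates.items():
            d[f"gate_{k}"] = v
        return pd.DataFrame(d)

    def summary(self) -> dict:
        return {
            "gc_nS": self.gc,
            "folds": [{"V_mV": v, "I_pA": i} for v, i in self.folds],
            "hopf": [{"V_mV": v, "I_pA": i} for v, i in self.hopf],
        }


def steady_state_curve(model: Model, V_range=(-80.0, 30.0), n_points: int = 2001,
                       gc: Optional[float] = None) -> SteadyStateCurve:
    """Sample the steady-state curve on a uniform V grid with both stability labels."""
    if n_points < 3:
        raise InputError("n_points must be >= 3")
    lo, hi = V_range
    if not hi > lo:
        raise InputError("V_range must be increasing and non-degenerate")
    if gc is None:
        gc = model.gc_default
    V = np.linspace(lo, hi, n_points)
    I_eq = np.asarray(model.equilibrium_current(V), float)
    gates = {k: np.asarray(v, float) for k, v in model.gating_steady_state(V).items()}
    dim = model.state_dim
    eig_cc = np.empty((n_points, dim), complex)
    eig_vc = np.empty((n_points, dim), complex)
    for i, v in enumerate(V):
        J = _jacobian(model, v, "CC")
        eig_cc[i] = np.sort_complex(np.linalg.eigvals(J))
        J[0, 0] -= gc / model.capacitance
        eig_vc[i] = np.sort_complex(np.linalg.eigvals(J))
    curve = SteadyStateCurve(
        V=V, I_eq=I_eq, Vh=V + I_eq / gc, gates=gates,
        eig_cc=eig_cc, eig_vc=eig_vc,
        stable_cc=eig_cc.real.max(axis=1) < 0,
        stable_vc=eig_vc.real.max(axis=1) < 0,
        gc=gc, model=model,
    )
    curve.folds = find_folds(curve)
    curve.hopf = find_hopf(curve)
    return curve


def find_folds(curve: SteadyStateCurve) -> list:
    """Folds (saddle-nodes): zeros of dI_eq/dV, bisection-refined; [(V, I), ...] by V."""
    if len(curve.V) < 3:
        raise InputError("curve needs at least 3 points")
    model = curve.model
    if model is not None:
        h = 1e-5

        def deriv(v):
            return float(model.equilibrium_current(v + h) - model.equilibrium_current(v - h)) / (2 * h)

        d = np.array([deriv(v) for v in curve.V])
        folds = []
        for i in np.nonzero(np.diff(np.sign(d)) != 0)[0]:
            v = brentq(deriv, curve.V[i], curve.V[i + 1], xtol=1e-12)
            folds.append((float(v), float(model.equilibrium_current(v))))
        return folds
    # no model attached: refine on a cubic spline through the sampled points
    sp = CubicSpline(curve.V, curve.I_eq)
    roots = sp.derivative().roots(extrapolate=False)
    return [(float(r), float(sp(r))) for r in np.sort(roots)]


def _max_complex_re(eigs: np.ndarray, tol: float = 1e-9) -> float:
    """Max real part over eigenvalues with nonzero imaginary part (nan if all real)."""
    mask = np.abs(eigs.imag) > tol
    if not mask.any():
        return np.nan
    return float(eigs.real[mask].max())


def find_hopf(curve: SteadyStateCurve) -> list:
    """Hopf candidates: crossings of Re of a complex eigenvalue pair of the CC Jacobian."""
    f = np.array([_max_complex_re(e) for e in curve.eig_cc])
    model = curve.model
    out = []
    for i in range(len(f) - 1):
        a, b = f[i], f[i + 1]
        if np.isnan(a) or np.isnan(b) or np.sign(a) == np.sign(b) or a == b:
            continue
        va, vb = curve.V[i], curve.V[i + 1]
        if model is not None:
            def g(v):
                return _max_complex_re(stability_eigenvalues(model, v, "CC"))
            # bisection robust to the function becoming undefined (real spectrum)
            for _ in range(60):
                vm = 0.5 * (va + vb)
                fm = g(vm)
                if np.isnan(fm):
                    break
                if np.sign(fm) == np.sign(a):
                    va = vm
                else:
                    vb = vm
            v = 0.5 * (va + vb)
            out.append((float(v), float(model.equilibrium_current(v))))
        else:
            v = va + (vb - va) * a / (a - b)
            out.append((float(v), float(np.interp(v, curve.V, curve.I_eq))))
    return out


# ---------------------------------------------------------------------------
# Brute-force attractor scan
# ---------------------------------------------------------------------------

@dataclass
class AttractorScan:
    """Per-current classification of long-run behavior under constant drive."""

    Ih: np.ndarray
    classification: list          # "rest" | "spiking" | "bistable"
    V_min: np.ndarray             # spiking envelope (nan where not spiking)
    V_max: np.ndarray
    mean_isi: np.ndarray          # ms (nan where not spiking)
    flags: list                   # "" or reason the point could not be validated
    I_db: Optional[float]         # largest scanned current with firing
    bistable_intervals: list      # [(I_lo, I_hi), ...]

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({
            "Ih_pA": self.Ih, "class": self.classification,
            "V_min_mV": self.V_min, "V_max_mV": self.V_max,
            "mean_isi_ms": self.mean_isi, "flag": self.flags,
        })

    def summary(self) -> dict:
        return {
            "I_db_pA": self.I_db,
            "bistable_intervals_pA": [list(b) for b in self.bistable_intervals],
            "n_flagged": sum(1 for f in self.flags if f),
        }


def _equilibria(model: Model, Ih: float, V_span=(-100.0, 40.0), n: int = 1401):
    """All solutions of I_eq(V) = Ih in V_span, with their CC stability."""
    Vg = np.linspace(*V_span, n)
    r = np.asarray(model.equilibrium_current(Vg), float) - Ih
    roots = []
    for i in np.nonzero(np.diff(np.sign(r)) != 0)[0]:
        v = brentq(lambda x: float(model.equilibrium_current(x)) - Ih,
                   Vg[i], Vg[i + 1], xtol=1e-10)
        stable = stability_eigenvalues(model, v, "CC").real.max() < 0
        roots.append((float(v), bool(stable)))
    return roots


def _count_upcrossings(V: np.ndarray, thr: float = SPIKE_THRESHOLD) -> int:
    above = V >= thr
    return int(np.count_nonzero(~above[:-1] & above[1:]))


def _classify_run(t: np.ndarray, V: np.ndarray):
    """Classify the trailing half of one constant-current run."""
    half = len(t) // 2
    th, Vh_ = t[half:], V[half:]
    up = np.nonzero((Vh_[:-1] < SPIKE_THRESHOLD) & (Vh_[1:] >= SPIKE_THRESHOLD))[0]
    if len(up) >= 3:
        isi = np.diff(th[up])
        flag = "" if len(isi) >= 4 else "few-spikes"
        return "spiking", float(Vh_.min()), float(Vh_.max()), float(isi.mean()), flag
    tail = V[int(0.9 * len(V)):]
    flag = "" if np.ptp(tail) < 1.0 else "not-settled"
    return "rest", np.nan, np.nan, np.nan, flag


def attractor_scan(model: Model, Ih_grid: Sequence[float], T: float = 2000.0,
                   n_inits: int = 2, sample_dt: float = 0.25) -> AttractorScan:
    """Brute-force scan of attractors over a grid of constant hold currents.

    For each current the model is integrated for ``T`` ms from an
    equilibrium-adjacent initial condition (the stable equilibrium if one
    exists, slightly perturbed) and from a spike-adjacent one (depolarized
    voltage with hyperpolarized gate values); divergent classifications mark
    bistability between firing and rest.
    """
    Ih_grid = np.asarray(Ih_grid, float)
    t_eval = np.arange(0.0, T + sample_dt / 2, sample_dt)
    n = len(Ih_grid)
    cls, flags = [], []
    V_min = np.full(n, np.nan)
    V_max = np.full(n, np.nan)
    isi = np.full(n, np.nan)

    spike_gates = model.dynamic_gate_steady_state(-65.0)

    for k, Ih in enumerate(Ih_grid):
        eqs = _equilibria(model, Ih)
        stable_eqs = [v for v, s in eqs if s]
        if stable_eqs:
            v_eq = stable_eqs[0]
        elif eqs:
            v_eq = eqs[0][0]
        else:
            v_eq = -65.0
        inits = [
            np.concatenate([[v_eq + 0.1], model.dynamic_gate_steady_state(v_eq)]),
            np.concatenate([[0.0], spike_gates]),
        ]
        for j in range(2, n_inits):
            inits.append(np.concatenate([[v_eq + 5.0 * (j - 1)],
                                         model.dynamic_gate_steady_state(v_eq)]))

        results = []
        for y0 in inits[:max(2, n_inits)]:
            f = _make_rhs(model, lambda _t, _V, Ih=Ih: Ih)
            sol = solve_ivp(f, (0.0, T), y0, method="LSODA", t_eval=t_eval,
                            rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise SimulationError(f"attractor scan failed at Ih={Ih} pA: {sol.message}")
            results.append(_classify_run(sol.t, sol.y[0]))

        kinds = {r[0] for r in results}
        flag = ";".join(sorted({r[4] for r in results if r[4]}))
        if kinds == {"spiking"}:
            c = "spiking"
        elif kinds == {"rest"}:
            c = "rest"
        else:
            c = "bistable"
        for kind, vmin, vmax, mi, _fl in results:
            if kind == "spiking":
                V_min[k], V_max[k], isi[k] = vmin, vmax, mi
                break
        cls.append(c)
        flags.append(flag)

    firing_any = [i for i, c in enumerate(cls) if c in ("spiking", "bistable")]
    I_db = float(Ih_grid[max(firing_any)]) if firing_any else None

    bist = []
    start = None
    for i, c in enumerate(cls + ["_end"]):
        if c == "bistable" and start is None:
            start = i
        elif c != "bistable" and start is not None:
            bist.append((float(Ih_grid[start]), float(Ih_grid[i - 1])))
            start = None

    return AttractorScan(Ih=Ih_grid, classification=cls, V_min=V_min, V_max=V_max,
                         mean_isi=isi, flags=flags, I_db=I_db,
                         bistable_intervals=bist)
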