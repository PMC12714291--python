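"""Conductance-based membrane models.

A neuron is described by the usual current-balance equation

    C dV/dt = -sum_j I_j(x_j, V) + I_ext,
    tau_j(V) dx_j/dt = phi_j * (x_inf_j(V) - x_j),

with membrane potential ``V`` (mV), membrane capacitance ``C`` (pF), ionic
currents ``I_j = g_max * prod(x^p) * (V - E_rev)`` (pA) gated by dimensionless
variables ``x`` with voltage-dependent steady states ``x_inf(V)`` and time
constants ``tau(V)`` (ms), and an external current ``I_ext`` (pA).

Units are fixed package-wide to mV, ms, pA, nS, pF, which makes the equation
dimensionally closed (pA/pF = mV/ms).  Built-in models are the Morris-Lecar
model in its class-I and class-II excitability parameterizations and the
Wang-Buzsaki interneuron model; both are declared as data (gate-law
identifiers plus parameters) so that they can be serialized to config files
and handed to the compiled integrator.

Note on the Morris-Lecar recovery gate: the relaxation time is
``tau_w(V) = 1 / cosh((V - V3) / (2 V4))``, the canonical (reciprocal-cosh)
form, so that ``dw/dt = phi (w_inf - w) cosh((V - V3)/(2 V4))``.

Note on the Wang-Buzsaki sodium gate: activation ``m`` is treated as
instantaneous (``m = m_inf(V)``, entering as ``m_inf^3``); only inactivation
``h`` and the potassium gate ``n`` are dynamic, so the state vector is
``(V, h, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InputError

__all__ = [
    "GatingLaw",
    "IonicCurrent",
    "Model",
    "ModelState",
    "make_morris_lecar",
    "make_wang_buzsaki",
    "make_leak_model",
    "get_model",
    "model_from_config",
    "BUILTIN_MODELS",
    "gating_steady_state",
    "equilibrium_current",
    "rhs",
]

# Gate-law identifiers (shared with the compiled stepper in _stepper.py).
LAW_TANH = 0        # x_inf = (1 + tanh((V - p0)/p1)) / 2, instantaneous
LAW_TANH_SECH = 1   # same x_inf; tau = 1 / cosh((V - p0) / (2 p1))
LAW_WB_M = 2        # Wang-Buzsaki sodium activation (alpha/beta rates)
LAW_WB_H = 3        # Wang-Buzsaki sodium inactivation
LAW_WB_N = 4        # Wang-Buzsaki potassium activation

_LAW_NAMES = {
    LAW_TANH: "tanh",
    LAW_TANH_SECH: "tanh_sech",
    LAW_WB_M: "wb_m",
    LAW_WB_H: "wb_h",
    LAW_WB_N: "wb_n",
}
_LAW_IDS = {v: k for k, v in _LAW_NAMES.items()}


def _lin_over_expm1(u, s):
    """u / (1 - exp(-s*u)) with the removable singularity at u=0 filled by its limit."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = u / (-np.expm1(-s * u))
    lim = 1.0 / s + u / 2.0
    return np.where(np.abs(s * u) < 1e-8, lim, out)


# Wang-Buzsaki rate functions (1/ms); the alpha_m and alpha_n numerators have
# removable singularities handled by _lin_over_expm1.
def _wb_alpha_m(V):
    return 0.1 * _lin_over_expm1(np.asarray(V, float) + 35.0, 0.1)


def _wb_beta_m(V):
    return 4.0 * np.exp(-0.0556 * (np.asarray(V, float) + 60.0))


def _wb_alpha_h(V):
    return 0.07 * np.exp(-0.05 * (np.asarray(V, float) + 58.0))


def _wb_beta_h(V):
    return 1.0 / (1.0 + np.exp(-0.1 * (np.asarray(V, float) + 28.0)))


def _wb_alpha_n(V):
    return 0.01 * _lin_over_expm1(np.asarray(V, float) + 34.0, 0.1)


def _wb_beta_n(V):
    return 0.125 * np.exp(-0.0125 * (np.asarray(V, float) + 44.0))


_WB_RATES = {
    LAW_WB_M: (_wb_alpha_m, _wb_beta_m),
    LAW_WB_H: (_wb_alpha_h, _wb_beta_h),
    LAW_WB_N: (_wb_alpha_n, _wb_beta_n),
}


@dataclass(frozen=True)
class GatingLaw:
    """One gating variable: steady state, relaxation time, and how it enters the conductance.

    ``rate_scale`` is the dimensionless temperature-like factor phi multiplying
    the relaxation rate; ``exponent`` is the power of the gate in the
    conductance product; ``dynamic=False`` marks gates evaluated at their
    steady state (instantaneous gates, not part of the state vector).
    """

    name: str
    law: int
    params: tuple[float, ...] = ()
    rate_scale: float = 1.0
    exponent: int = 1
    dynamic: bool = True

    def __post_init__(self):
        if self.law not in _LAW_NAMES:
            raise InputError(f"unknown gate law id {self.law!r}")
        if self.exponent < 1:
            raise InputError("gate exponent must be >= 1")
        if self.law in (LAW_TANH, LAW_TANH_SECH) and len(self.params) != 2:
            raise InputError(f"law {_LAW_NAMES[self.law]!r} needs params (V_half, slope)")

    def steady_state(self, V):
        """x_inf(V), dimensionless in [0, 1]."""
        V = np.asarray(V, dtype=float)
        if self.law in (LAW_TANH, LAW_TANH_SECH):
            v0, k = self.params
            return 0.5 * (1.0 + np.tanh((V - v0) / k))
        alpha, beta = _WB_RATES[self.law]
        a, b = alpha(V), beta(V)
        return a / (a + b)

    def time_constant(self, V):
        """tau(V) in ms (strictly positive); 1/(alpha+beta) for rate-based laws."""
        V = np.asarray(V, dtype=float)
        if self.law == LAW_TANH:
            return np.ones_like(V)
        if self.law == LAW_TANH_SECH:
            v0, k = self.params
            return 1.0 / np.cosh((V - v0) / (2.0 * k))
        alpha, beta = _WB_RATES[self.law]
        return 1.0 / (alpha(V) + beta(V))

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "law": _LAW_NAMES[self.law],
            "params": list(self.params),
            "rate_scale": self.rate_scale,
            "exponent": self.exponent,
            "dynamic": self.dynamic,
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "GatingLaw":
        law = cfg["law"]
        if law not in _LAW_IDS:
            raise InputError(f"unknown gate law {law!r}")
        return cls(
            name=cfg["name"],
            law=_LAW_IDS[law],
            params=tuple(cfg.get("params", ())),
            rate_scale=float(cfg.get("rate_scale", 1.0)),
            exponent=int(cfg.get("exponent", 1)),
            dynamic=bool(cfg.get("dynamic", True)),
        )


@dataclass(frozen=True)
class IonicCurrent:
    """One ionic current g_max * prod(gate^exponent) * (V - E_rev), in pA."""

    name: str
    g_max: float   # nS
    E_rev: float   # mV
    gates: tuple[GatingLaw, ...] = ()

    def __post_init__(self):
        if self.g_max < 0:
            raise InputError(f"current {self.name!r}: g_max must be >= 0")
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise InputError(f"current {self.name!r}: duplicate gate names")

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "g_max_nS": self.g_max,
            "E_rev_mV": self.E_rev,
            "gates": [g.to_config() for g in self.gates],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "IonicCurrent":
        return cls(
            name=cfg["name"],
            g_max=float(cfg["g_max_nS"]),
            E_rev=float(cfg["E_rev_mV"]),
            gates=tuple(GatingLaw.from_config(g) for g in cfg.get("gates", ())),
        )


@dataclass(frozen=True)
class ModelState:
    """State vector (V, dynamic gate values)."""

    V: float
    gates: tuple[float, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([self.V, *self.gates], dtype=float)


@dataclass(frozen=True)
class Model:
    """A conductance-based membrane model: capacitance plus a set of ionic currents.

    The state vector layout is (V, x_1, ..., x_n) where x_i are the dynamic
    gates in order of appearance across ``currents``.  ``gc_default`` carries
    the feedback gain (nS) the voltage-clamp protocol uses by default for this
    cell type.
    """

    name: str
    capacitance: float  # pF
    currents: tuple[IonicCurrent, ...]
    gc_default: float = 40.0  # nS

    def __post_init__(self):
        if self.capacitance <= 0:
            raise InputError("capacitance must be > 0")
        names = [g.name for c in self.currents for g in c.gates]
        if len(set(names)) != len(names):
            raise InputError("gate names must be unique across currents")

    # -- structure -----------------------------------------------------------

    @property
    def dynamic_gates(self) -> tuple[GatingLaw, ...]:
        return tuple(g for c in self.currents for g in c.gates if g.dynamic)

    @property
    def all_gates(self) -> tuple[GatingLaw, ...]:
        return tuple(g for c in self.currents for g in c.gates)

    @property
    def state_dim(self) -> int:
        return 1 + len(self.dynamic_gates)

    # -- evaluation ----------------------------------------------------------

    def gating_steady_state(self, V) -> dict[str, np.ndarray]:
        """x_inf(V) for every gate (dynamic and instantaneous), keyed by gate name."""
        return {g.name: g.steady_state(V) for g in self.all_gates}

    def dynamic_gate_steady_state(self, V) -> np.ndarray:
        """x_inf(V) for the dynamic gates only, in state-vector order."""
        return np.array([g.steady_state(V) for g in self.dynamic_gates], dtype=float)

    def equilibrium_state(self, V: float) -> ModelState:
        return ModelState(float(V), tuple(self.dynamic_gate_steady_state(V)))

    def ionic_current(self, V, dyn_gates=None, g_scale: float = 1.0):
        """Total ionic current (pA) at voltage V.

        Dynamic gates are taken from ``dyn_gates`` (state-vector order); if
        None, every gate sits at its steady state, which yields the
        equilibrium current I_eq(V).  ``g_scale`` uniformly scales all maximal
        conductances (used for slow drift emulation).
        """
        V = np.asarray(V, dtype=float)
        total = np.zeros_like(V)
        i_dyn = 0
        for cur in self.currents:
            act = np.ones_like(V)
            for gate in cur.gates:
                if gate.dynamic and dyn_gates is not None:
                    x = dyn_gates[i_dyn]
                else:
                    x = gate.steady_state(V)
                if gate.dynamic:
                    i_dyn += 1
                act = act * np.asarray(x, dtype=float) ** gate.exponent
            total = total + g_scale * cur.g_max * act * (V - cur.E_rev)
        return total

    def equilibrium_current(self, V):
        """I_eq(V): total ionic current with every gate at steady state (pA)."""
        return self.ionic_current(V, dyn_gates=None)

    def rhs(self, state, I_ext: float, g_scale: float = 1.0) -> np.ndarray:
        """Time derivative of (V, x_1, ..., x_n) for external current I_ext (pA)."""
        y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
        if y.shape != (self.state_dim,):
            raise InputError(
                f"state dimension {y.shape} does not match model "
                f"({self.state_dim},)"
            )
        V = y[0]
        dyn = y[1:]
        dV = (-self.ionic_current(V, dyn, g_scale=g_scale) + I_ext) / self.capacitance
        out = np.empty_like(y)
        out[0] = dV
        for i, gate in enumerate(self.dynamic_gates):
            out[1 + i] = gate.rate_scale * (gate.steady_state(V) - dyn[i]) / gate.time_constant(V)
        return out

    # -- serialization -------------------------------------------------------

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "capacitance_pF": self.capacitance,
            "gc_default_nS": self.gc_default,
            "currents": [c.to_config() for c in self.currents],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "Model":
        return cls(
            name=cfg.get("name", "custom"),
            capacitance=float(cfg["capacitance_pF"]),
            gc_default=float(cfg.get("gc_default_nS", 40.0)),
            currents=tuple(IonicCurrent.from_config(c) for c in cfg["currents"]),
        )

    # -- packing for the compiled stepper -------------------------------------

    def pack(self) -> dict[str, np.ndarray]:
        """Flatten the model into plain arrays for the numba stepper."""
        gmax, erev = [], []
        law, p0, p1, expo, cur_idx, dyn_slot, phi = [], [], [], [], [], [], []
        slot = 0
        for ci, cur in enumerate(self.currents):
            gmax.append(cur.g_max)
            erev.append(cur.E_rev)
            for gate in cur.gates:
                law.append(gate.law)
                pr = gate.params + (0.0, 0.0)
                p0.append(pr[0])
                p1.append(pr[1] if pr[1] != 0.0 else 1.0)
                expo.append(gate.exponent)
                cur_idx.append(ci)
                if gate.dynamic:
                    dyn_slot.append(slot)
                    slot += 1
                else:
                    dyn_slot.append(-1)
                phi.append(gate.rate_scale)
        return {
            "C": float(self.capacitance),
            "gmax": np.asarray(gmax, float),
            "erev": np.asarray(erev, float),
            "law": np.asarray(law, np.int64),
            "p0": np.asarray(p0, float),
            "p1": np.asarray(p1, float),
            "expo": np.asarray(expo, np.int64),
            "cur_idx": np.asarray(cur_idx, np.int64),
            "dyn_slot": np.asarray(dyn_slot, np.int64),
            "phi": np.asarray(phi, float),
        }


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

# Morris-Lecar parameters: C gL VL gCa VCa gK VK gc phi V1 V2 V3 V4
_ML_PARAMS = {
    "I": dict(C=20.0, gL=2.0, VL=-60.0, gCa=4.0, VCa=120.0, gK=12.0, VK=-84.0,
              gc=40.0, phi=0.067, V1=-1.2, V2=18.0, V3=12.0, V4=17.4),
    "II": dict(C=20.0, gL=2.0, VL=-60.0, gCa=4.4, VCa=120.0, gK=12.0, VK=-84.0,
               gc=150.0, phi=0.040, V1=-1.2, V2=18.0, V3=2.0, V4=30.0),
}


def make_morris_lecar(excitability_class: str = "I") -> Model:
    """Morris-Lecar model; ``excitability_class`` is "I" or "II".

    Calcium activation m is instantaneous; the potassium recovery gate w is
    the single dynamic gate, so the state vector is (V, w).
    """
    if excitability_class not in _ML_PARAMS:
        raise InputError(
            f"unknown Morris-Lecar excitability class {excitability_class!r}; "
            'expected "I" or "II"'
        )
    p = _ML_PARAMS[excitability_class]
    return Model(
        name=f"morris_lecar_{excitability_class}",
        capacitance=p["C"],
        gc_default=p["gc"],
        currents=(
            IonicCurrent("L", p["gL"], p["VL"]),
            IonicCurrent(
                "Ca", p["gCa"], p["VCa"],
                gates=(GatingLaw("m", LAW_TANH, (p["V1"], p["V2"]), dynamic=False),),
            ),
            IonicCurrent(
                "K", p["gK"], p["VK"],
                gates=(GatingLaw("w", LAW_TANH_SECH, (p["V3"], p["V4"]),
                                 rate_scale=p["phi"]),),
            ),
        ),
    )


def make_wang_buzsaki() -> Model:
    """Wang-Buzsaki interneuron model (state vector (V, h, n))."""
    phi = 5.0
    return Model(
        name="wang_buzsaki",
        capacitance=1.0,
        gc_default=20.0,
        currents=(
            IonicCurrent("L", 0.1, -65.0),
            IonicCurrent(
                "Na", 35.0, 55.0,
                gates=(
                    GatingLaw("m", LAW_WB_M, exponent=3, dynamic=False),
                    GatingLaw("h", LAW_WB_H, rate_scale=phi),
                ),
            ),
            IonicCurrent(
                "K", 9.0, -90.0,
                gates=(GatingLaw("n", LAW_WB_N, exponent=4, rate_scale=phi),),
            ),
        ),
    )


def make_leak_model(gL: float = 2.0, VL: float = -60.0, C: float = 20.0) -> Model:
    """Passive single-current model gL*(V - VL); linear test fixture with closed forms."""
    if gL <= 0:
        raise InputError("gL must be > 0")
    if C <= 0:
        raise InputError("C must be > 0")
    return Model(
        name="leak",
        capacitance=C,
        gc_default=40.0,
        currents=(IonicCurrent("L", gL, VL),),
    )


BUILTIN_MODELS = ("morris_lecar_I", "morris_lecar_II", "wang_buzsaki", "leak")


def get_model(name: str) -> Model:
    """Resolve a built-in model by name."""
    if name == "morris_lecar_I":
        return make_morris_lecar("I")
    if name == "morris_lecar_II":
        return make_morris_lecar("II")
    if name == "wang_buzsaki":
        return make_wang_buzsaki()
    if name == "leak":
        return make_leak_model()
    raise InputError(f"unknown model {name!r}; built-ins: {BUILTIN_MODELS}")


def model_from_config(cfg) -> Model:
    """Build a Model from a config mapping, or resolve a built-in by name."""
    if isinstance(cfg, str):
        return get_model(cfg)
    if "name" in cfg and len(cfg) == 1:
        return get_model(cfg["name"])
    return Model.from_config(cfg)


# ---------------------------------------------------------------------------
# Module-level operation aliases
# ---------------------------------------------------------------------------

def gating_steady_state(model: Model, V):
    """x_inf(V) for every gate of ``model``, keyed by gate name."""
    return model.gating_steady_state(V)


def equilibrium_current(model: Model, V):
    """I_eq(V) = total ionic current with all gates at steady state (pA)."""
    return model.equilibrium_current(V)


def rhs(model: Model, state, I_ext: float):
    """State derivative of ``model`` at ``state`` under external current ``I_ext``."""
    return model.rhs(state, I_ext)
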