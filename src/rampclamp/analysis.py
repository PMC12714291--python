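"""From raw clamp recordings to an experimental bifurcation diagram.

The pipeline mirrors how experimental slow-ramp data are read:

* the voltage-clamp (VC) recording is smoothed with a centered moving median
  (default window 0.2 s at 20 kHz) and paired with the hold voltage to give
  the measured S-shaped curve (Ivc_sm(Vh), Vh);
* instability of a curve segment is asserted either (i) topologically, from
  a negative slope dIvc_sm/dVh of a more heavily smoothed copy of the curve
  (default window 0.75 s), or (ii) circumstantially, from the presence of
  slow-fast oscillations (firing) in the current-clamp (CC) run at matching
  currents;
* the segment between the low fold and the onset of firing carries no
  evidence either way from a single up-ramp and is labeled "undetermined";
* fold markers sit at the boundaries of the negative-slope region; a Hopf
  marker is placed at the depolarization-block current I_db only when the
  firing amplitude collapses before the block (small-amplitude oscillations
  near the block), otherwise the block onset is reported unclassified;
* first-order ramp-speed biases are estimated from the half-decay time
  tau_1/2 of transients: voltage lag = ramp_speed * tau_half / ln 2 for the
  VC ramp, and bias(Vmin) = dVmin/dIh * dIh/dt * tau_half / ln 2 for the CC
  ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import EstimationError, InconsistencyError, InputError
from .protocols import Recording

__all__ = [
    "MeasuredCurve",
    "StabilityLabeling",
    "ExperimentalDiagram",
    "TransientFit",
    "SpikeTrain",
    "DropoutEvent",
    "AnalysisOptions",
    "smooth",
    "build_vc_curve",
    "negative_slope_labels",
    "detect_spikes",
    "detect_depolarization_block",
    "firing_onset_current",
    "slow_phase_mask",
    "phase_plane_embedding",
    "estimate_tau_half",
    "vc_bias_estimate",
    "cc_bias_estimate",
    "vc_as_cc_ramp_speed",
    "recast_vc_to_cc",
    "detect_dropouts",
    "assemble_diagram",
]

LN2 = math.log(2.0)

#: default smoothing windows, seconds
CURVE_WINDOW_S = 0.2
SLOPE_WINDOW_S = 0.75


# ---------------------------------------------------------------------------
# smoothing and the measured curve
# ---------------------------------------------------------------------------

def smooth(series, window: int, kind: str = "median") -> np.ndarray:
    """Centered moving median/mean with shrinking windows at the edges.

    ``window`` is a sample count; even values are rounded up to the next odd
    number so the window is symmetric.  Output length equals input length.
    """
    x = np.asarray(series, float)
    n = len(x)
    if window < 1:
        raise InputError("window must be >= 1")
    if window > n:
        raise InputError(f"window {window} exceeds series length {n}")
    if window % 2 == 0:
        window += 1
    window = min(window, n if n % 2 else n - 1) if n > 1 else 1
    if kind not in ("median", "mean"):
        raise InputError(f"kind must be 'median' or 'mean', got {kind!r}")
    r = pd.Series(x).rolling(window, center=True, min_periods=1)
    out = (r.median() if kind == "median" else r.mean()).to_numpy()
    # shrink edge windows symmetrically (and keep them odd), so a monotone
    # input maps to itself under the median and a ramp survives the mean
    f = np.median if kind == "median" else np.mean
    for i in range(min(window // 2, n - 1 - window // 2)):
        out[i] = f(x[:2 * i + 1])
        out[n - 1 - i] = f(x[n - 1 - 2 * i:])
    return out


@dataclass
class MeasuredCurve:
    """Smoothed measured VC curve (Ivc_sm(Vh), Vh) with the raw current kept for diagnostics."""

    t: np.ndarray
    Vh: np.ndarray          # ascending
    I_raw: np.ndarray
    I_sm: np.ndarray        # moving median, window `window`
    I_sm_large: np.ndarray  # moving median, window `window_large` (slope criterion)
    window: int
    window_large: int
    sample_dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.Vh)
        if not all(len(a) == n for a in (self.t, self.I_raw, self.I_sm, self.I_sm_large)):
            raise InputError("curve arrays must have equal length")
        if self.window_large < self.window:
            raise InputError("window_large must be >= window")

    @property
    def ramp_speed(self) -> float:
        """Hold-voltage ramp speed, mV/ms."""
        return float((self.Vh[-1] - self.Vh[0]) / (self.t[-1] - self.t[0]))

    def slope(self) -> np.ndarray:
        """dI_sm_large/dVh by central differences over a half-window baseline, pA/mV.

        Adjacent samples of a slow ramp are fractions of a microvolt apart,
        so the difference baseline is widened to half the slope-criterion
        window; edges fall back to one-sided differences.
        """
        k = max(1, self.window_large // 2)
        n = len(self.Vh)
        hi = np.minimum(np.arange(n) + k, n - 1)
        lo = np.maximum(np.arange(n) - k, 0)
        return (self.I_sm_large[hi] - self.I_sm_large[lo]) / (self.Vh[hi] - self.Vh[lo])


def build_vc_curve(rec: Recording, window: Optional[int] = None,
                   window_large: Optional[int] = None) -> MeasuredCurve:
    """Pair the smoothed VC current with the hold voltage.

    The hold-voltage command must be strictly ascending (single up-ramp;
    down-ramps / hysteresis protocols are rejected).  Window defaults are
    0.2 s and 0.75 s converted to samples via the recording's sampling step.
    """
    if rec.mode != "VC":
        raise InputError(f"expected a VC recording, got mode {rec.mode!r}")
    dv = np.diff(rec.command)
    if np.any(dv < 0):
        raise InputError("hold-voltage command must be ascending (down-ramps unsupported)")
    if np.any(dv == 0):
        raise InputError("hold-voltage command must be strictly monotone")
    dt = rec.sample_dt
    if window is None:
        window = int(round(CURVE_WINDOW_S * 1000.0 / dt))
    if window_large is None:
        window_large = int(round(SLOPE_WINDOW_S * 1000.0 / dt))
    window = min(window, len(rec.I)) | 1
    window_large = min(window_large, len(rec.I)) | 1
    return MeasuredCurve(
        t=rec.t, Vh=rec.command, I_raw=rec.I,
        I_sm=smooth(rec.I, window, "median"),
        I_sm_large=smooth(rec.I, window_large, "median"),
        window=window, window_large=window_large, sample_dt=dt,
        meta=dict(rec.metadata),
    )


def negative_slope_labels(curve: MeasuredCurve, min_run: float = 1.0) -> np.ndarray:
    """Boolean mask of points unstable by the negative-slope criterion.

    A point qualifies when dI_sm_large/dVh < 0 over a contiguous run at least
    ``min_run`` mV wide.  Qualifying runs separated by a gap narrower than
    ``min_run`` (e.g. a single dropout interrupting the middle branch) are
    merged; sub-threshold flickers from residual noise are discarded.
    """
    neg = curve.slope() < 0.0
    keep = [(a, b) for a, b in _runs(neg) if curve.Vh[b - 1] - curve.Vh[a] >= min_run]
    # artifacts are correlated over the slope-smoothing window, so gaps up to
    # its extent in Vh (or min_run, if larger) are treated as interruptions
    dvh = (curve.Vh[-1] - curve.Vh[0]) / max(len(curve.Vh) - 1, 1)
    merge_gap = max(min_run, curve.window_large * dvh)
    merged = []
    for a, b in keep:
        if merged and curve.Vh[a] - curve.Vh[merged[-1][1] - 1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = np.zeros_like(neg)
    for a, b in merged:
        out[a:b] = True
    return out


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


# ---------------------------------------------------------------------------
# spikes, block, slow phase, embeddings
# ---------------------------------------------------------------------------

class SpikeTrain(NamedTuple):
    times: np.ndarray   # ms
    isis: np.ndarray    # ms


def detect_spikes(rec: Recording, threshold: float = -10.0,
                  refractory: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings separated by at least the refractory time."""
    if rec.mode != "CC":
        raise InputError(f"expected a CC recording, got mode {rec.mode!r}")
    V = rec.V
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    times = []
    last = -np.inf
    for i in up:
        t = rec.t[i + 1]
        if t - last >= refractory:
            times.append(t)
            last = t
    times = np.asarray(times)
    return SpikeTrain(times, np.diff(times))


def _sustained_bounds(times: np.ndarray, window: float = 2000.0, k: int = 2):
    """First and last spike index belonging to a sustained episode.

    A spike is "sustained" when ``k`` further spikes follow (resp. precede)
    within ``window`` ms; isolated spikes evoked by disturbance pulses while
    the cell is merely excitable do not qualify.  Returns None when no
    sustained episode exists.
    """
    n = len(times)
    if n < k + 1:
        return None
    first = next((i for i in range(n - k) if times[i + k] - times[i] <= window), None)
    last = next((j for j in range(n - 1, k - 1, -1) if times[j] - times[j - k] <= window),
                None)
    if first is None or last is None:
        return None
    return first, last


def detect_depolarization_block(rec: Recording, spikes: SpikeTrain,
                                sustained_window: float = 2000.0) -> Optional[float]:
    """I_db: hold current at the last sustained spike of an ascending ramp.

    Isolated trailing spikes (e.g. evoked by dropout pulses above the block)
    are ignored; with fewer than three spikes the last spike is used.
    Returns None when the run is silent.
    """
    if len(spikes.times) == 0:
        return None
    b = _sustained_bounds(spikes.times, sustained_window)
    t_last = spikes.times[b[1]] if b is not None else spikes.times[-1]
    return float(np.interp(t_last, rec.t, rec.command))


def firing_onset_current(rec: Recording, spikes: SpikeTrain,
                         sustained_window: float = 2000.0) -> Optional[float]:
    """Hold current at the first sustained spike (None when the run is silent)."""
    if len(spikes.times) == 0:
        return None
    b = _sustained_bounds(spikes.times, sustained_window)
    t_first = spikes.times[b[0]] if b is not None else spikes.times[0]
    return float(np.interp(t_first, rec.t, rec.command))


def slow_phase_mask(rec: Recording, threshold_fraction: float = 0.01,
                    smooth_ms: float = 1.0) -> np.ndarray:
    """Flag samples where the trajectory moves slowly in the (V', V'') sense.

    The norm |(V'(t) dt, V''(t) dt)| is computed from smoothed finite
    differences and compared against ``threshold_fraction`` times its trace
    maximum.
    """
    dt = rec.sample_dt
    w = max(1, int(round(smooth_ms / dt)))
    Vs = smooth(rec.V, w, "mean")
    v1 = np.gradient(Vs, dt)
    v1s = smooth(v1, w, "mean")
    v2 = np.gradient(v1s, dt)
    norm = np.hypot(v1s * dt, v2 * dt)
    if norm.max() == 0.0:  # motionless trace: everything is slow
        return np.ones(len(norm), bool)
    return norm < threshold_fraction * norm.max()


def phase_plane_embedding(rec: Recording):
    """(V, V') pairs using a one-step forward difference; length n-1."""
    dV = np.diff(rec.V) / rec.sample_dt
    return rec.V[:-1], dV


# ---------------------------------------------------------------------------
# transient fits and bias estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientFit:
    """Half-decay time of a transient toward a stable (spiking) state."""

    tau_half: float    # ms
    n_peaks: int
    asymptote: float   # mV
    residual: float    # mV RMS


def _segment_maxima(rec: Recording, spikes: Optional[SpikeTrain]):
    """Per-spike voltage maxima (value, time); falls back to local maxima of the trace."""
    if spikes is not None and len(spikes.times) >= 2:
        edges = np.concatenate([[rec.t[0]],
                                (spikes.times[:-1] + spikes.times[1:]) / 2,
                                [rec.t[-1] + rec.sample_dt]])
        vals, times = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (rec.t >= a) & (rec.t < b)
            if not sel.any():
                continue
            i = np.argmax(rec.V[sel])
            vals.append(rec.V[sel][i])
            times.append(rec.t[sel][i])
        return np.asarray(vals), np.asarray(times)
    peaks, _ = find_peaks(rec.V)
    return rec.V[peaks], rec.t[peaks]


def estimate_tau_half(rec: Recording, spikes: Optional[SpikeTrain] = None,
                      min_peaks: int = 4, rel_floor: float = 0.05) -> TransientFit:
    """Extract tau_1/2 from the decay of voltage maxima toward their asymptote.

    The asymptote is the mean of the last quartile of maxima; the remaining
    deviations |max_k - asymptote| are fit as A * 2^(-t_k / tau_half) by
    least squares on the log2 scale.  Deviations below ``rel_floor`` times
    the largest one are dropped (they are dominated by noise).
    """
    vals, times = _segment_maxima(rec, spikes)
    if len(vals) < min_peaks:
        raise EstimationError(f"need at least {min_peaks} maxima, found {len(vals)}")
    nq = max(1, len(vals) // 4)
    asym = float(vals[-nq:].mean())
    d = np.abs(vals[:-nq] - asym)
    tt = times[:-nq]
    use = d > max(rel_floor * d.max(), 1e-12)
    if use.sum() < min_peaks:
        raise EstimationError(f"need at least {min_peaks} usable maxima, found {int(use.sum())}")
    y = np.log2(d[use])
    slope, intercept = np.polyfit(tt[use], y, 1)
    if slope >= 0:
        raise EstimationError("voltage maxima do not decay toward the asymptote")
    tau = -1.0 / slope
    fit = 2.0 ** (intercept + slope * tt[use])
    resid = float(np.sqrt(np.mean((d[use] - fit) ** 2)))
    return TransientFit(tau_half=float(tau), n_peaks=int(use.sum()),
                        asymptote=asym, residual=resid)


class BiasEstimate(NamedTuple):
    voltage_mV: float
    current_pA: float


def vc_bias_estimate(ramp_speed: float, tau_half: float, dIeq_dV: Optional[float] = None):
    """First-order voltage lag of the VC ramp: ramp_speed * tau_half / ln 2 (mV).

    ``ramp_speed`` in mV/ms, ``tau_half`` in ms.  When the local curve slope
    dIeq/dV (pA/mV) is given, the corresponding current bias is returned too.
    """
    v = ramp_speed * tau_half / LN2
    if dIeq_dV is None:
        return v
    return BiasEstimate(voltage_mV=v, current_pA=v * dIeq_dV)


def cc_bias_estimate(dVmin_dI: float, ramp_speed: float, tau_half: float) -> float:
    """First-order bias of the spike-minimum voltage under the CC ramp (mV).

    bias(Vmin) = dVmin/dIh (mV/pA) * dIh/dt (pA/ms) * tau_half (ms) / ln 2.
    """
    return dVmin_dI * ramp_speed * tau_half / LN2


def vc_as_cc_ramp_speed(dI_dVh: float, dVh_dt: float) -> float:
    """Current ramp speed (pA/ms) of the VC run recast as a CC protocol.

    The slowly varying measured current Ivc_sm obeys dIvc_sm/dt =
    (dIvc_sm/dVh) * dVh/dt; with the fast-scale voltage speed this bounds how
    fast the equivalent CC drive moves.
    """
    return dI_dVh * dVh_dt


def recast_vc_to_cc(curve: MeasuredCurve):
    """Recast a measured VC curve as a CC current schedule (t, Ih(t), dIh/dt)."""
    dIdt = np.gradient(curve.I_sm, curve.t)
    return curve.t, curve.I_sm, dIdt


# ---------------------------------------------------------------------------
# dropouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropoutEvent:
    onset_ms: float
    duration_ms: float
    peak_pA: float


def detect_dropouts(curve: MeasuredCurve, k_mad: float = 6.0,
                    merge_gap_ms: float = 5.0) -> list:
    """Intermittent clamp-dropout events: residual excursions beyond k_mad robust SDs.

    The residual is raw minus smoothed current; its scale is the median
    absolute deviation (scaled to an SD).  Flagged samples separated by less
    than ``merge_gap_ms`` belong to the same event (the clamp response rings
    briefly after a pulse).
    """
    resid = curve.I_raw - curve.I_sm
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(resid) or 1.0
    mask = np.abs(resid) > k_mad * scale
    gap = max(1, int(round(merge_gap_ms / curve.sample_dt)))
    raw_runs = _runs(mask)
    merged = []
    for a, b in raw_runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    events = []
    for a, b in merged:
        seg = resid[a:b]
        events.append(DropoutEvent(
            onset_ms=float(curve.t[a]),
            duration_ms=float((b - a) * curve.sample_dt),
            peak_pA=float(seg[np.argmax(np.abs(seg))]),
        ))
    return events


# ---------------------------------------------------------------------------
# diagram assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable parameters of the diagram assembly."""

    min_run_mV: float = 1.0              # minimum extent of a negative-slope run
    spike_threshold: float = -10.0       # mV
    refractory_ms: float = 2.0
    slow_threshold_fraction: float = 0.01
    hopf_small_amp_fraction: float = 0.25
    voltage_match_tol: float = 10.0      # mV, CC-rest vs curve match
    sustained_window_ms: float = 2000.0  # episode window for onset/block detection
    tau_half_vc: float = 75.0            # ms, VC recovery half-time for the bias bound
    tau_half_cc: float = 200.0           # ms, CC transient half-time
    k_mad: float = 6.0
    envelope_window_s: float = 0.2


@dataclass
class StabilityLabeling:
    """Per-point stability labels with the evidence basis and bifurcation markers."""

    label: np.ndarray    # "stable" | "unstable" | "undetermined"
    basis: np.ndarray    # "none" | "slope" | "oscillation-evidence"
    folds: list          # [(Vh, I), ...] geometric turning points
    hopf: list           # [(Vh, I)] at the block when amplitude collapses
    block_onset: Optional[tuple] = None  # (Vh, I) unclassified block marker

    def segments(self, Vh: np.ndarray, I: np.ndarray) -> list:
        out = []
        start = 0
        for i in range(1, len(self.label) + 1):
            if i == len(self.label) or self.label[i] != self.label[start] \
                    or self.basis[i] != self.basis[start]:
                out.append({
                    "label": str(self.label[start]),
                    "basis": str(self.basis[start]),
                    "Vh_mV": [float(Vh[start]), float(Vh[i - 1])],
                    "I_pA": [float(I[start]), float(I[i - 1])],
                })
                start = i
        return out


@dataclass
class Envelope:
    """Spiking envelope of the CC run, binned over the smoothing window."""

    I: np.ndarray
    V_min: np.ndarray
    V_max: np.ndarray


@dataclass
class ExperimentalDiagram:
    """The assembled experimental bifurcation diagram."""

    curve: MeasuredCurve
    labeling: StabilityLabeling
    cc_t: np.ndarray
    cc_I: np.ndarray
    cc_V_sm: np.ndarray
    envelope: Optional[Envelope]
    spikes: SpikeTrain
    onset_I: Optional[float]
    I_db: Optional[float]
    slow_mask: np.ndarray
    drift_metric: float          # pA
    bias_vc_mV: float
    bias_cc_mV: float
    dVmin_dI: float              # mV/pA
    dropouts: list

    def to_json(self) -> dict:
        lab = self.labeling
        return {
            "segments": lab.segments(self.curve.Vh, self.curve.I_sm),
            "folds": [{"Vh_mV": v, "I_pA": i} for v, i in lab.folds],
            "hopf": [{"Vh_mV": v, "I_pA": i} for v, i in lab.hopf],
            "block_onset": (
                {"Vh_mV": lab.block_onset[0], "I_pA": lab.block_onset[1]}
                if lab.block_onset else None),
            "I_db_pA": self.I_db,
            "onset_I_pA": self.onset_I,
            "drift_metric_pA": self.drift_metric,
            "bias_vc_mV": self.bias_vc_mV,
            "bias_cc_mV": self.bias_cc_mV,
            "dVmin_dI_mV_per_pA": self.dVmin_dI,
            "n_dropouts": len(self.dropouts),
        }

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Vh_mV": self.curve.Vh,
            "I_sm_pA": self.curve.I_sm,
            "label": self.labeling.label,
            "basis": self.labeling.basis,
        })


def _rest_voltage_by_current(rec: Recording, spikes: SpikeTrain, window_s: float):
    """Binned (Ih, V) pairs of the quiescent parts of the CC run."""
    dt = rec.sample_dt
    nb = max(1, int(round(window_s * 1000.0 / dt)))
    n = len(rec.t) // nb
    I_b, V_b = [], []
    for k in range(n):
        sl = slice(k * nb, (k + 1) * nb)
        t0, t1 = rec.t[sl.start], rec.t[sl.stop - 1]
        if len(spikes.times) and np.any((spikes.times >= t0 - 50.0) & (spikes.times <= t1 + 50.0)):
            continue
        I_b.append(rec.I[sl].mean())
        V_b.append(np.median(rec.V[sl]))
    return np.asarray(I_b), np.asarray(V_b)


def _spiking_envelope(rec: Recording, spikes: SpikeTrain, window_s: float):
    if len(spikes.times) < 3:
        return None
    dt = rec.sample_dt
    nb = max(1, int(round(window_s * 1000.0 / dt)))
    t0, t1 = spikes.times[0], spikes.times[-1]
    i0, i1 = int(t0 / dt), int(t1 / dt)
    I, vmin, vmax = [], [], []
    for a in range(i0, i1 - nb + 1, nb):
        sl = slice(a, a + nb)
        I.append(rec.I[sl].mean())
        vmin.append(rec.V[sl].min())
        vmax.append(rec.V[sl].max())
    if not I:
        return None
    return Envelope(np.asarray(I), np.asarray(vmin), np.asarray(vmax))


def _spike_amplitudes(rec: Recording, spikes: SpikeTrain):
    """Peak-to-trough amplitude of each firing cycle."""
    amps = []
    tm = spikes.times
    for a, b in zip(tm[:-1], tm[1:]):
        sel = (rec.t >= a) & (rec.t < b)
        if sel.any():
            amps.append(np.ptp(rec.V[sel]))
    return np.asarray(amps)


def assemble_diagram(vc: MeasuredCurve, cc: Recording,
                     opts: AnalysisOptions = AnalysisOptions()) -> ExperimentalDiagram:
    """Overlay the VC curve and the CC run into a labeled bifurcation diagram.

    Stability labels follow the two evidence rules (negative slope of the
    heavily smoothed curve; firing in the CC run at matching currents); the
    segment between the low fold and the firing onset is "undetermined".
    Markers: folds at the negative-slope-region boundaries; a Hopf candidate
    at I_db when the firing amplitude collapses before the block.  No marker
    is ever placed at an undetermined/unstable boundary.
    """
    if cc.mode != "CC":
        raise InputError(f"expected a CC recording, got mode {cc.mode!r}")
    n = len(vc.Vh)
    label = np.full(n, "stable", dtype=object)
    basis = np.full(n, "none", dtype=object)

    # criterion (i): negative slope
    slope_mask = negative_slope_labels(vc, opts.min_run_mV)
    label[slope_mask] = "unstable"
    basis[slope_mask] = "slope"

    runs = _runs(slope_mask)
    folds = []
    for a, b in runs:
        folds.append((float(vc.Vh[a]), float(vc.I_sm[a])))
        folds.append((float(vc.Vh[b - 1]), float(vc.I_sm[b - 1])))
    folds.sort()
    low_fold_Vh = folds[0][0] if folds else None
    upper_fold_Vh = folds[-1][0] if folds else None

    # CC evidence
    spikes = detect_spikes(cc, opts.spike_threshold, opts.refractory_ms)
    I_db = detect_depolarization_block(cc, spikes, opts.sustained_window_ms)
    if len(spikes.times) and I_db is None:  # pragma: no cover - defensive
        raise InconsistencyError("spikes detected but no block current could be assigned")
    onset_I = firing_onset_current(cc, spikes, opts.sustained_window_ms)

    # criterion (ii): oscillation evidence on the branch above the upper fold
    if onset_I is not None and upper_fold_Vh is not None:
        osc = (~slope_mask) & (vc.Vh > upper_fold_Vh) \
            & (vc.I_sm >= onset_I) & (vc.I_sm <= I_db)
        label[osc] = "unstable"
        basis[osc] = "oscillation-evidence"

    # undetermined: above the low fold, below the firing onset, no evidence
    rest_I, rest_V = _rest_voltage_by_current(cc, spikes, opts.envelope_window_s)
    if low_fold_Vh is not None:
        cand = (label == "stable") & (vc.Vh > low_fold_Vh)
        if onset_I is not None:
            cand &= vc.I_sm < onset_I
        elif len(rest_I):
            # silent CC run: only points confirmed by a matching rest state stay stable
            matched = np.zeros(n, bool)
            for i in np.flatnonzero(cand):
                j = np.argmin(np.abs(rest_I - vc.I_sm[i]))
                if abs(rest_V[j] - vc.Vh[i]) <= opts.voltage_match_tol:
                    matched[i] = True
            cand &= ~matched
        label[cand] = "undetermined"

    # markers: Hopf at the block only when the firing amplitude collapses
    hopf = []
    block_onset = None
    if I_db is not None and len(spikes.times) >= 7:
        amps = _spike_amplitudes(cc, spikes)
        v_at_block = float(np.interp(I_db, vc.I_sm[vc.Vh > (upper_fold_Vh or vc.Vh[0])],
                                     vc.Vh[vc.Vh > (upper_fold_Vh or vc.Vh[0])])) \
            if upper_fold_Vh is not None else float("nan")
        if len(amps) >= 6 and amps[-5:].mean() < opts.hopf_small_amp_fraction * amps.max():
            hopf.append((v_at_block, float(I_db)))
        else:
            block_onset = (v_at_block, float(I_db))

    labeling = StabilityLabeling(label=label, basis=basis, folds=folds,
                                 hopf=hopf, block_onset=block_onset)

    # overlays and derived quantities
    cc_V_sm = smooth(cc.V, min(vc.window, len(cc.V)) | 1, "mean")
    env = _spiking_envelope(cc, spikes, opts.envelope_window_s)
    slow = slow_phase_mask(cc, opts.slow_threshold_fraction)

    # drift between the VC curve and the CC rest branch (shared stable low
    # branch); the curve is compared at the reconstructed membrane voltage
    # V = Vh - Ivc/gc so that the clamp offset is not mistaken for drift
    drift = float("nan")
    gc = vc.meta.get("gc")
    v_mem = vc.Vh - vc.I_sm / gc if gc else vc.Vh
    if low_fold_Vh is not None:
        lo_sel = rest_V < low_fold_Vh
    else:
        lo_sel = np.ones(len(rest_V), bool)
    if lo_sel.any():
        vlo = (vc.Vh <= (low_fold_Vh if low_fold_Vh is not None else vc.Vh[-1]))
        if vlo.sum() >= 2:
            i_vc = np.interp(rest_V[lo_sel], v_mem[vlo], vc.I_sm[vlo])
            drift = float(np.median(np.abs(i_vc - rest_I[lo_sel])))

    bias_vc = vc_bias_estimate(vc.ramp_speed, opts.tau_half_vc)
    dvmin_di = float("nan")
    bias_cc = float("nan")
    cc_rate = float((cc.command[-1] - cc.command[0]) / (cc.t[-1] - cc.t[0])) \
        if cc.t[-1] > cc.t[0] else 0.0
    if env is not None and len(env.I) >= 3:
        dvmin_di = float(np.polyfit(env.I, env.V_min, 1)[0])
        bias_cc = cc_bias_estimate(dvmin_di, cc_rate, opts.tau_half_cc)

    return ExperimentalDiagram(
        curve=vc, labeling=labeling,
        cc_t=cc.t, cc_I=cc.I, cc_V_sm=cc_V_sm,
        envelope=env, spikes=spikes, onset_I=onset_I, I_db=I_db,
        slow_mask=slow, drift_metric=drift,
        bias_vc_mV=float(bias_vc), bias_cc_mV=float(bias_cc),
        dVmin_dI=dvmin_di, dropouts=detect_dropouts(vc, opts.k_mad),
    )
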