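"""Run configuration: one YAML/JSON file describing model, protocols and analysis.

Field names carry their units (``ramp_speed_mV_per_s``); ramp speeds are
given per second in config files (the natural bench scale) and converted to
the package's per-millisecond units at load time.  The voltage-clamp gain
may be given either directly (``gc_nS``) or as a feedback resistor
(``feedback_resistor_MOhm``; gc = 1/Rf, so 500 MOhm -> 2 nS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .analysis import AnalysisOptions
from .errors import ConfigError
from .fixtures import DriftConfig
from .models import Model, model_from_config
from .protocols import CCProtocol, DisturbanceConfig, StepProtocol, VCProtocol

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    model: Model
    vc: Optional[VCProtocol] = None
    cc: Optional[CCProtocol] = None
    step: Optional[StepProtocol] = None
    disturbance: Optional[DisturbanceConfig] = None
    drift: DriftConfig = field(default_factory=DriftConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: Optional[int] = None
    output_dir: Path = Path(".")


def _req(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigError(f"{where}.{key}: required field missing")
    return section[key]


def _num(section: dict, key: str, where: str, default=None):
    v = section.get(key, default)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ConfigError(f"{where}.{key}: expected a number, got {v!r}") from None


def _vc_from(sec: dict) -> VCProtocol:
    gc = _num(sec, "gc_nS", "vc")
    rf = _num(sec, "feedback_resistor_MOhm", "vc")
    if gc is not None and rf is not None:
        raise ConfigError("vc: give gc_nS or feedback_resistor_MOhm, not both")
    if rf is not None:
        if rf <= 0:
            raise ConfigError("vc.feedback_resistor_MOhm: must be > 0")
        gc = 1000.0 / rf  # 1/Rf with Rf in MOhm gives gc in nS
    return VCProtocol(
        Vh_start=_num(sec, "Vh_start_mV", "vc", -80.0),
        Vh_end=_num(sec, "Vh_end_mV", "vc", 30.0),
        ramp_speed=_num(sec, "ramp_speed_mV_per_s", "vc", 1.83) / 1000.0,
        gc=gc,
        sample_dt=_num(sec, "sample_dt_ms", "vc", 0.05),
    )


def _cc_from(sec: dict) -> CCProtocol:
    return CCProtocol(
        Ih_start=_num(sec, "Ih_start_pA", "cc", 0.0),
        Ih_end=_num(sec, "Ih_end_pA", "cc", 420.0),
        ramp_speed=_num(sec, "ramp_speed_pA_per_s", "cc", 7.0) / 1000.0,
        sample_dt=_num(sec, "sample_dt_ms", "cc", 0.05),
    )


def _step_from(sec: dict) -> StepProtocol:
    return StepProtocol(
        baseline_I=_num(sec, "baseline_pA", "step", 0.0),
        step_I=_num(sec, "step_pA", "step", 200.0),
        t_on=_num(sec, "t_on_ms", "step", 100.0),
        t_off=_num(sec, "t_off_ms", "step", 1600.0),
        total_T=_num(sec, "total_T_ms", "step", 2000.0),
        sample_dt=_num(sec, "sample_dt_ms", "step", 0.05),
    )


def _dist_from(sec: dict, seed) -> DisturbanceConfig:
    return DisturbanceConfig(
        noise_sd=_num(sec, "noise_sd_pA", "disturbance", 0.0),
        dropout_rate=_num(sec, "dropout_rate_per_s", "disturbance", 0.0),
        dropout_amplitude=_num(sec, "dropout_amplitude_pA", "disturbance", 0.0),
        dropout_duration=_num(sec, "dropout_duration_ms", "disturbance", 0.0),
        seed=sec.get("seed", seed),
    )


def _analysis_from(sec: dict) -> AnalysisOptions:
    kw = {}
    allowed = {f: f for f in AnalysisOptions.__dataclass_fields__}
    for k, v in sec.items():
        if k not in allowed:
            raise ConfigError(f"analysis.{k}: unknown field")
        kw[k] = v
    try:
        return AnalysisOptions(**kw)
    except TypeError as e:
        raise ConfigError(f"analysis: {e}") from None


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: not valid YAML/JSON ({e})") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    seed = raw.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")

    model_sec = _req(raw, "model", "(top level)")
    try:
        model = model_from_config(model_sec)
    except Exception as e:
        raise ConfigError(f"model: {e}") from None

    cfg = RunConfig(model=model, seed=seed,
                    output_dir=Path(raw.get("output_dir", ".")))
    if "vc" in raw:
        cfg.vc = _vc_from(raw["vc"] or {})
    if "cc" in raw:
        cfg.cc = _cc_from(raw["cc"] or {})
    if "step" in raw:
        cfg.step = _step_from(raw["step"] or {})
    if "disturbance" in raw:
        cfg.disturbance = _dist_from(raw["disturbance"] or {}, seed)
    if "drift" in raw:
        try:
            cfg.drift = DriftConfig(float((raw["drift"] or {}).get("relative_drift", 0.0)))
        except Exception as e:
            raise ConfigError(f"drift: {e}") from None
    if "analysis" in raw:
        cfg.analysis = _analysis_from(raw["analysis"] or {})
    return cfg
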