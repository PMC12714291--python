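"""Synthetic paired VC/CC/step recordings with known ground truth.

The generator emulates the statistical structure of minute-long 20 kHz
patch-clamp recordings: additive white current noise, intermittent square
"dropout" current pulses at Poisson times, and a slow deterministic drift of
the cell's conductances over each protocol run.  Defaults follow the
experimental protocol (VC ramp 1.83 mV/s from -80 to +30 mV; CC ramp 7 pA/s
from 0 pA over 60 s; a 200 pA calibration step) with disturbance magnitudes
chosen at a realistic patch-clamp scale (noise ~5 pA, dropouts ~100 pA for
a few ms, a couple percent conductance drift per run); the experimental
reference does not pin these magnitudes down, so they are exposed as free
parameters.

Ground truth (the steady-state curve) is always computed on the undrifted
model; the drifted truth at any time is derivable from the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError, InputError
from .ground_truth import AttractorScan, SteadyStateCurve, attractor_scan, steady_state_curve
from .models import model_from_config
from .protocols import (
    CCProtocol, DisturbanceConfig, Recording, StepProtocol, VCProtocol,
    simulate_cc, simulate_step, simulate_vc,
)

__all__ = ["DriftConfig", "FixtureBundle", "make_fixture", "DEFAULT_DISTURBANCE"]

#: realistic default disturbance scale (seed is filled in by make_fixture)
DEFAULT_DISTURBANCE = dict(noise_sd=5.0, dropout_rate=0.5,
                           dropout_amplitude=100.0, dropout_duration=5.0)


@dataclass(frozen=True)
class DriftConfig:
    """Slow deterministic drift: all maximal conductances scaled by 1 + relative_drift * t/T."""

    relative_drift: float = 0.0

    def __post_init__(self):
        if abs(self.relative_drift) >= 0.5:
            raise InputError("|relative_drift| must be < 0.5")


@dataclass
class FixtureBundle:
    """Paired recordings from one synthetic cell plus its ground truth."""

    vc: Recording
    cc: Recording
    step: Recording
    truth: SteadyStateCurve
    scan: Optional[AttractorScan]
    manifest: dict

    def write(self, outdir) -> Path:
        from .io import write_recording
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, rec in (("vc", self.vc), ("cc", self.cc), ("step", self.step)):
            write_recording(rec, outdir / f"{name}.tsv")
        self.truth.to_table().to_csv(outdir / "truth_curve.tsv", sep="\t", index=False)
        if self.scan is not None:
            self.scan.to_table().to_csv(outdir / "truth_scan.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def make_fixture(model_name: str = "morris_lecar_I",
                 vc: Optional[VCProtocol] = None,
                 cc: Optional[CCProtocol] = None,
                 step: Optional[StepProtocol] = None,
                 dist: Optional[DisturbanceConfig] = None,
                 drift: DriftConfig = DriftConfig(),
                 seed: int = 0,
                 include_attractor_scan: bool = False,
                 outdir=None) -> FixtureBundle:
    """Generate a paired VC/CC/step fixture with known ground truth.

    All three recordings come from the same (drifting) cell; per-recording
    noise realizations use independent streams derived from ``seed``.  The
    steady-state curve is computed on the undrifted model.  The brute-force
    attractor scan is expensive and seed-independent, so it is only run when
    ``include_attractor_scan`` is set.
    """
    model = model_from_config(model_name)
    vc = vc or VCProtocol()
    cc = cc or CCProtocol()
    step = step or StepProtocol()
    sub_seeds = [int(s) for s in
                 np.random.SeedSequence(seed).generate_state(2, np.uint64) % (2 ** 31)]
    if dist is None:
        dist = DisturbanceConfig(seed=sub_seeds[0], **DEFAULT_DISTURBANCE)
    elif dist.active and dist.seed is None:
        raise ConfigError("disturbance with nonzero magnitudes needs a seed")
    vc_dist = DisturbanceConfig(dist.noise_sd, dist.dropout_rate, dist.dropout_amplitude,
                                dist.dropout_duration, seed=sub_seeds[0])
    cc_dist = DisturbanceConfig(dist.noise_sd, dist.dropout_rate, dist.dropout_amplitude,
                                dist.dropout_duration, seed=sub_seeds[1])

    rd = drift.relative_drift
    vc_rec = simulate_vc(model, vc, vc_dist, relative_drift=rd)
    cc_rec = simulate_cc(model, cc, cc_dist, relative_drift=rd)
    step_rec = simulate_step(model, step)
    truth = steady_state_curve(model, gc=vc.gc if vc.gc is not None else model.gc_default)
    scan = None
    if include_attractor_scan:
        grid = np.arange(min(cc.Ih_start, cc.Ih_end),
                         max(cc.Ih_start, cc.Ih_end) + 1.0, 5.0)
        scan = attractor_scan(model, grid, T=1000.0)

    manifest = {
        "model": model.to_config(),
        "protocols": {"vc": asdict(vc), "cc": asdict(cc), "step": asdict(step)},
        "disturbance": asdict(dist),
        "drift": asdict(drift),
        "seed": seed,
        "sub_seeds": sub_seeds,
        "checksums": {
            "vc": _checksum(vc_rec.t, vc_rec.V, vc_rec.I),
            "cc": _checksum(cc_rec.t, cc_rec.V, cc_rec.I),
            "step": _checksum(step_rec.t, step_rec.V, step_rec.I),
        },
    }
    bundle = FixtureBundle(vc_rec, cc_rec, step_rec, truth, scan, manifest)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
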