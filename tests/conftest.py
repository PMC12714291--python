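import numpy as np
import pytest

from rampclamp import (
    CCProtocol, DisturbanceConfig, VCProtocol,
    assemble_diagram, build_vc_curve, get_model,
    simulate_cc, simulate_vc, steady_state_curve,
)


@pytest.fixture(scope="session")
def ml1():
    return get_model("morris_lecar_I")


@pytest.fixture(scope="session")
def ml2():
    return get_model("morris_lecar_II")


@pytest.fixture(scope="session")
def wb():
    return get_model("wang_buzsaki")


@pytest.fixture(scope="session")
def leak():
    return get_model("leak")


@pytest.fixture(scope="session")
def ml1_curve(ml1):
    return steady_state_curve(ml1)


@pytest.fixture(scope="session")
def ml2_curve(ml2):
    return steady_state_curve(ml2)


@pytest.fixture(scope="session")
def ml1_noisy_pair(ml1):
    """One noisy VC/CC pair over a reduced ramp range (shared across analysis tests)."""
    dist = DisturbanceConfig(noise_sd=5.0, dropout_rate=0.5, dropout_amplitude=100.0,
                             dropout_duration=5.0, seed=123)
    vc = simulate_vc(ml1, VCProtocol(Vh_start=-80.0, Vh_end=10.0), dist)
    cc = simulate_cc(ml1, CCProtocol(Ih_start=0.0, Ih_end=280.0),
                     DisturbanceConfig(noise_sd=5.0, dropout_rate=0.5,
                                       dropout_amplitude=100.0, dropout_duration=5.0,
                                       seed=321))
    return vc, cc


@pytest.fixture(scope="session")
def ml1_diagram(ml1_noisy_pair):
    vc, cc = ml1_noisy_pair
    return assemble_diagram(build_vc_curve(vc), cc)


def truth_folds_measured(curve):
    """Ground-truth fold locations mapped into the measured (Vh, I) coordinates."""
    return [(v + i / curve.gc, i) for v, i in curve.folds]


def diagram_accuracy(diagram, truth):
    """Fraction of asserted (non-undetermined) labels agreeing with ground truth,
    outside +-2 mV neighborhoods of the true folds; also the undetermined fraction."""
    mcurve = diagram.curve
    lab = diagram.labeling.label
    truth_unstable = np.interp(mcurve.Vh, truth.Vh,
                               (~truth.stable_cc).astype(float)) > 0.5
    excl = np.zeros(len(mcurve.Vh), bool)
    for vh, _ in truth_folds_measured(truth):
        excl |= np.abs(mcurve.Vh - vh) < 2.0
    claimed = (lab != "undetermined") & ~excl
    acc = float(np.mean((lab == "unstable")[claimed] == truth_unstable[claimed]))
    return acc, float(np.mean(lab == "undetermined"))
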