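import numpy as np
import pytest

from hgfilter import _fast
from hgfilter.binary import (
    BinaryHGFParams,
    BinaryInputModel,
    filter_sequence_binary,
)
from hgfilter.continuous import InitialBelief, TrialSeries
from hgfilter.recovery import make_input_sequence
from hgfilter.responses import ResponseModelSpec, ResponseParams, simulate_responses


@pytest.fixture(scope="session", autouse=True)
def _compiled_filter():
    """Trigger JIT compilation once so individual tests time evenly."""
    _fast.warm_up()


@pytest.fixture(scope="session")
def input_sequence():
    """Shared 320-trial block-structured binary input sequence."""
    return make_input_sequence(320, None, seed=101)


@pytest.fixture(scope="session")
def simulated_subject(input_sequence):
    """A simulated agent (kappa=1.5, low decision noise) and its choices.

    Returns (series with responses, true parameter dict, trajectory).
    """
    true = {"kappa": 1.5, "omega": -4.0, "theta": 0.0025,
            "mu2_0": 0.0, "sigma2_0": 1.0, "mu3_0": 1.0, "sigma3_0": 1.0,
            "zeta": 24.0}
    params = BinaryHGFParams(kappa=true["kappa"], omega=true["omega"],
                             theta=true["theta"])
    init = InitialBelief(mu0=(true["mu2_0"], true["mu3_0"]),
                         sigma0=(true["sigma2_0"], true["sigma3_0"]))
    traj = filter_sequence_binary(TrialSeries(u=input_sequence), params,
                                  BinaryInputModel("noiseless"), init)
    y = simulate_responses(
        traj, ResponseModelSpec("unit_square_sigmoid", ResponseParams(true["zeta"])),
        seed=202)
    return TrialSeries(u=input_sequence, y=y), true, traj
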