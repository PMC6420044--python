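import numpy as np
import pytest

from effcond.cable import SynapticEvent, discretize
from effcond.experiments import InputSchedule, run_protocol
from effcond.fixtures import (E_KERNEL, I_KERNEL, SCAN_PEAKS, branched_neuron,
                              long_stick_neuron, point_neuron)
from effcond.morphology import build_ball_and_stick


@pytest.fixture(scope="session")
def point_model():
    return point_neuron()


@pytest.fixture(scope="session")
def ball_and_stick_model():
    return discretize(build_ball_and_stick(20.0, 400.0, 2.0), 10.0)


@pytest.fixture(scope="session")
def long_stick_model():
    return long_stick_neuron()


@pytest.fixture(scope="session")
def branched_model():
    return branched_neuron(seed=7)


def _pair_protocol(model, distance, peaks):
    site_E = model.nearest_compartment(distance)
    site_I = site_E
    events = [
        SynapticEvent(site_E, 10.0, peaks[0], *E_KERNEL[:2], 70.0, "E"),
        SynapticEvent(site_I, 10.0, peaks[1], *I_KERNEL[:2], -10.0, "I"),
    ]
    schedule = InputSchedule(events, 1, 1, rate=0.0, window=110.0, seed=0)
    return run_protocol(model, schedule, tail=100.0)


@pytest.fixture(scope="session")
def protocol_100um(long_stick_model):
    """Co-located 2.5/4 nS pair 100 μm out: the dynamic-clamp condition."""
    return _pair_protocol(long_stick_model, 100.0,
                          (E_KERNEL[2], I_KERNEL[2]))


@pytest.fixture(scope="session")
def protocol_distal(long_stick_model):
    """Small-conductance pair far out on the main dendrite."""
    return _pair_protocol(long_stick_model, 1600.0, SCAN_PEAKS)
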