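import numpy as np
import pytest

from intermit import (ControllerSpec, PrimitiveShape, TrackingTask,
                      build_H_tracking, simulate, step_target,
                      sum_of_sines_target)
from intermit.core import AccumulatorSpec

DT60 = 1.0 / 60.0


@pytest.fixture
def shape():
    return PrimitiveShape()


def tracking_controller(k=20.0, sigma_a=0.0, sigma_m=0.0, Kprime=1.0):
    """Noise-configurable cursor-tracking controller with tracking H."""
    spec = ControllerSpec(tau_p=0.05, Kprime=Kprime, sigma_m=sigma_m,
                          accumulator=AccumulatorSpec(k=k, sigma_a=sigma_a))
    spec.H = build_H_tracking(spec.shape, spec.tau_p)
    return spec


@pytest.fixture
def step_trace():
    """Noise-free response to a unit step target at the recording rate."""
    ctl = tracking_controller()
    return simulate(ctl, TrackingTask(step_target(1.0, 2.0, DT60)), 2.0,
                    dt=DT60, seed=0), ctl


@pytest.fixture(scope="session")
def sines_trace():
    """Noise-free sum-of-sines tracking run, shared across tests."""
    ctl = tracking_controller()
    tgt = sum_of_sines_target(60.0, DT60, seed=11)
    return simulate(ctl, TrackingTask(tgt), 60.0, dt=DT60, seed=0), ctl, tgt
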