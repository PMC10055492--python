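import numpy as np
import pytest

from kinpost.simulator import (
    KineticParams,
    build_frame_schedule,
    make_prior,
    make_reference_curve,
)


@pytest.fixture(scope="session")
def schedule():
    return build_frame_schedule()


@pytest.fixture(scope="session")
def ref_curve(schedule):
    return make_reference_curve(total_duration=schedule.total_duration)


@pytest.fixture(scope="session")
def prior1():
    return make_prior(1)


@pytest.fixture(scope="session")
def default_params():
    """The study's default kinetic-parameter point."""
    return KineticParams(dvr=1.0, k2_per_min=0.0006, r1=0.74)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
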