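"""Shared fixtures: nominal parameter sets and the calibrated step amplitude."""

import numpy as np
import pytest

from polecarry import (
    ContactParams,
    ControlParams,
    LoadParams,
    NO_CONTROL,
    PoleLoadModel,
    PoleParams,
    calibrate_step_amplitude,
)


@pytest.fixture(scope="session")
def loads():
    return LoadParams(m1=10.0, m2=10.0)


@pytest.fixture(scope="session")
def contact():
    # kds=500, khs=10000 with damping ratio 0.25 against the carried mass
    return ContactParams.from_stiffness(500.0, 10000.0, m_ref=20.0, zeta=0.25)


@pytest.fixture(scope="session")
def control():
    return ControlParams(Kp=1000.0, Kd=500.0, Dh=0.3)


@pytest.fixture(scope="session")
def nsnr_pole():
    return PoleParams.make("NSNR", L=1.4)


@pytest.fixture(scope="session")
def nsnr_model(nsnr_pole, loads, contact):
    return PoleLoadModel(nsnr_pole, loads, contact, NO_CONTROL)


@pytest.fixture(scope="session")
def calibrated_amplitude(nsnr_pole, loads, contact):
    """Step amplitude driving the rigid pole to 15 deg at 1 s (no control)."""
    return calibrate_step_amplitude(
        nsnr_pole, loads, contact, target_angle=15.0, at_time=1.0
    )


def make_pole(variant, **kw):
    return PoleParams.make(variant, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260905)
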