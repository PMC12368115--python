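"""Shared fixtures: a default generator and its reference calibration.

The calibration fixture chain (noiseless 119-step bead stack -> detected
peaks -> fitted model) is session-scoped because several modules test
closure properties against it.
"""

import numpy as np
import pytest

from dhpsf.calibrate import build_calibration, extract_pair_features
from dhpsf.detect import DetectionParams, detect_stack
from dhpsf.pipeline import CAL_STEP_NM, default_generator
from dhpsf.simulate import simulate_calibration


@pytest.fixture(scope="session")
def gen():
    return default_generator()


@pytest.fixture(scope="session")
def cal_stack(gen):
    stack, zs = simulate_calibration(gen)
    return stack, zs


@pytest.fixture(scope="session")
def cal_peaks(gen, cal_stack):
    stack, _zs = cal_stack
    return detect_stack(stack, DetectionParams())


@pytest.fixture(scope="session")
def cal_features(gen, cal_peaks):
    return extract_pair_features(
        cal_peaks, CAL_STEP_NM, gen.pixel_size_nm, z0_nm=gen.z_range_nm[0]
    )


@pytest.fixture(scope="session")
def model(gen, cal_peaks):
    return build_calibration(
        cal_peaks, z_step_nm=CAL_STEP_NM, pixel_size_nm=gen.pixel_size_nm,
        degree=15, z0_nm=gen.z_range_nm[0],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
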