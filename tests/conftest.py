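"""Shared fixtures: synthetic hips at various morphologies.

Heavier hips are session-scoped and meshed coarsely where the check being
made is not a resolution study.
"""

import numpy as np
import pytest

from ffmkit import HipParams, RomLimits, build_hip_frame, generate_hip


def cranial_fovea(offset_deg: float, azimuth_deg: float = 0.0) -> tuple:
    """Fovea direction tilted ``offset_deg`` away from the cup axis (+y),
    toward cranial for azimuth 0, rotated about the cup axis otherwise."""
    off = np.radians(offset_deg)
    az = np.radians(azimuth_deg)
    d = np.array([np.sin(off) * np.sin(az), np.cos(off), np.sin(off) * np.cos(az)])
    return tuple(float(x) for x in d)


@pytest.fixture(scope="session")
def default_params() -> HipParams:
    return HipParams()


@pytest.fixture(scope="session")
def default_hip(default_params):
    return generate_hip(default_params)


@pytest.fixture(scope="session")
def offset_params() -> HipParams:
    # fovea 20 deg cranial to the fossa center: a clear, nonzero mismatch
    return HipParams(fovea_direction=cranial_fovea(20.0))


@pytest.fixture(scope="session")
def offset_hip(offset_params):
    return generate_hip(offset_params)


@pytest.fixture(scope="session")
def framed_offset_hip(offset_hip):
    pelvis, femur, truth = offset_hip
    frame, pelvis_c, femur_c = build_hip_frame(pelvis, femur)
    return frame, pelvis_c, femur_c, truth


@pytest.fixture(scope="session")
def coarse_offset_params() -> HipParams:
    return HipParams(fovea_direction=cranial_fovea(20.0), mesh_resolution=2.5)


@pytest.fixture(scope="session")
def rom() -> RomLimits:
    return RomLimits()
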