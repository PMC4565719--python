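"""Shared fixtures: synthetic specimens at test-friendly resolutions."""

import numpy as np
import pytest

from paleobody import SweepConfig
from paleobody import synthetic_specimen as synth

# coarse-but-accurate joint resolution used throughout the tests; rim and
# shaft faceting at this level shifts contact angles by well under the
# 1-degree sweep increment the tests use
JOINT_RES = dict(
    n_azimuth=48,
    n_polar=6,
    shaft_sections=24,
    shaft_rings=8,
    head_subdivisions=2,
)


@pytest.fixture(scope="session")
def toy_body():
    return synth.make_toy_body()


@pytest.fixture(scope="session")
def socket_joint():
    """No-lip hemispherical cup with a spherical-head bone."""
    return synth.make_socket_joint(**JOINT_RES)


@pytest.fixture(scope="session")
def lipped_joint():
    """Cup with a bony lip over the cranial sector (blocks protraction).

    Total coverage stays at 100 degrees so the overhanging lip clears the
    head at every tested joint space; polar rows are doubled because the lip
    widens the polar span each row must cover.
    """
    res = dict(JOINT_RES, n_polar=12)
    return synth.make_socket_joint(
        cup_half_angle_deg=80.0,
        lip=dict(azimuth_center_deg=90.0, azimuth_halfwidth_deg=35.0, extra_deg=20.0),
        **res,
    )


@pytest.fixture(scope="session")
def sweep_cfg():
    return SweepConfig(
        increment_deg=1.0, limit_deg=120.0, lar_limit_deg=360.0, joint_spaces_mm=(0.0, 1.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20150910)
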