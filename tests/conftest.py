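"""Shared fixtures: packaged case table, calibrated stiffness parameters,
and small analytic geometries."""
import numpy as np
import pytest

from spinesim import calibration as cal
from spinesim import model as md
from spinesim.geometry import SpineGeometry, VertebraGeometry, \
    vertebra_landmarks
from spinesim.io import load_packaged_cases
from spinesim.synthetic import generate_spine


@pytest.fixture(scope="session")
def cases():
    """The packaged 10-case clinical-index table."""
    rows = load_packaged_cases()
    assert len(rows) == 10
    return rows


@pytest.fixture(scope="session")
def case1(cases):
    return cases[0]


@pytest.fixture(scope="session")
def calibrated_params():
    """Stiffness parameters after FSU + release-partition calibration."""
    return cal.calibrate_release_partition(
        md.default_stiffness_params(), cal.default_fsu_targets())


@pytest.fixture(scope="session")
def case1_geometry(case1):
    return generate_spine(case1, seed=1)


@pytest.fixture(scope="session")
def case1_model(case1_geometry, calibrated_params):
    return md.assemble_model(case1_geometry, calibrated_params)


def straight_spine(n_tilt=None):
    """A straight vertical spine built from the default dimension table."""
    from spinesim import levels
    from spinesim.synthetic import (DISC_HEIGHT_FRACTION,
                                    vertebral_dimensions)
    dims = [vertebral_dimensions(lab, 165.0) for lab in levels.ALL_BODIES]
    z = 0.0
    bodies = []
    for j, lab in enumerate(levels.ALL_BODIES):
        if j > 0:
            disc = DISC_HEIGHT_FRACTION * 0.5 * (dims[j - 1][2] + dims[j][2])
            z -= 0.5 * dims[j - 1][2] + disc + 0.5 * dims[j][2]
        bodies.append(VertebraGeometry(
            lab, np.array([0.0, 0.0, z]), np.eye(3),
            vertebra_landmarks(*dims[j]), dims[j]))
    return SpineGeometry(bodies[:-1], bodies[-1])


@pytest.fixture()
def straight_geometry():
    return straight_spine()
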