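import math

import numpy as np
import pytest

from myogait import (
    GAIT_GRID,
    Joint,
    JointKinematics,
    MuscleTendonUnit,
    MusculoskeletalModel,
    PathPoint,
    Segment,
    default_curves,
)


@pytest.fixture(scope="session")
def curves():
    return default_curves()


def make_hinge_model(p: float = 1.0, d: float = 1.0, **unit_kwargs):
    """Single-hinge toy model: L(theta) = sqrt(p^2 + d^2 - 2 p d cos theta).

    Origin at radius p on the parent ray, insertion at radius d on the
    child ray of one revolute joint.
    """
    params = dict(F_o=100.0, L_o=0.1, V_max=10.0, alpha_o=0.0, L_s=0.5)
    params.update(unit_kwargs)
    unit = MuscleTendonUnit(
        name="toy",
        path=[PathPoint("ground", (p, 0.0, 0.0)),
              PathPoint("link", (d, 0.0, 0.0))],
        **params,
    )
    return MusculoskeletalModel(
        species="toy",
        segments=[Segment("ground"), Segment("link")],
        joints=[Joint(name="hinge", parent="ground", child="link")],
        units=[unit],
    )


def hinge_length(theta, p: float = 1.0, d: float = 1.0):
    """Closed-form toy-hinge muscle-tendon length."""
    return np.sqrt(p**2 + d**2 - 2 * p * d * np.cos(theta))


def hinge_moment_arm(theta, p: float = 1.0, d: float = 1.0):
    """Closed form -dL/dtheta of the toy hinge (flexor-positive convention)."""
    return -p * d * np.sin(theta) / hinge_length(theta, p, d)


@pytest.fixture
def hinge_model():
    return make_hinge_model()


def make_kinematics(angles_deg: dict, subject_id: str = "s1", **kwargs) -> JointKinematics:
    """Kinematics on the 101-sample grid from full-length or scalar values."""
    full = {}
    for k, v in angles_deg.items():
        v = np.asarray(v, dtype=float)
        full[k] = np.full_like(GAIT_GRID, float(v)) if v.ndim == 0 else v
    return JointKinematics(subject_id=subject_id, angles=full, **kwargs)


def compliant_unit(**kwargs) -> MuscleTendonUnit:
    """Unit with a long compliant tendon (L_o/L_s = 1/3)."""
    params = dict(
        name="compliant", F_o=500.0, L_o=0.05, V_max=10.0,
        alpha_o=math.radians(10.0), L_s=0.15,
        path=[PathPoint("a", (0, 0, 0)), PathPoint("b", (1, 0, 0))],
    )
    params.update(kwargs)
    return MuscleTendonUnit(**params)


def rigid_unit(**kwargs) -> MuscleTendonUnit:
    """Unit above the rigid-tendon threshold (L_o/L_s = 3)."""
    params = dict(
        name="rigid", F_o=100.0, L_o=0.09, V_max=10.0, alpha_o=0.0, L_s=0.03,
        path=[PathPoint("a", (0, 0, 0)), PathPoint("b", (1, 0, 0))],
    )
    params.update(kwargs)
    return MuscleTendonUnit(**params)
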