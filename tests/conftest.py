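import numpy as np
import pytest

from footkin.rhythms import build_default_rhythms, identity_rhythms
from footkin.skeleton import (
    JointSpec,
    KinematicTemplate,
    Segment,
    default_template,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def rhythms(template):
    return build_default_rhythms(template)


@pytest.fixture(scope="session")
def free_rhythms(template):
    return identity_rhythms(template)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_chain():
    """Two-link planar chain: base -> link1 (z-revolute) -> link2 (z-revolute)."""
    segments = [
        Segment("base", None),
        Segment(
            "link1",
            "base",
            local_joint_center=[0.0, 0.0, 0.0],
            marker_points={"M1": [0.5, 0.0, 0.0]},
        ),
        Segment(
            "link2",
            "link1",
            local_joint_center=[1.0, 0.0, 0.0],
            marker_points={"M2": [1.0, 0.0, 0.0], "M2b": [0.5, 0.1, 0.0]},
        ),
    ]
    joints = [
        JointSpec("link1", "revolute", [[0, 0, 1]], ("plantarflexion",)),
        JointSpec("link2", "revolute", [[0, 0, 1]], ("plantarflexion",)),
    ]
    return KinematicTemplate(segments, joints, name="toy-chain")
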