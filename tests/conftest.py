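import numpy as np
import pytest

from leafecho.acoustics import BeamSpec, Medium
from leafecho.geometry import DiscSet, SonarPose


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def medium():
    return Medium()


@pytest.fixture
def absorbing_medium():
    return Medium(absorption_enabled=True)


@pytest.fixture
def on_axis_pose():
    return SonarPose((0.0, 0.0, 0.0), (1.0, 0.0, 0.0),
                     BeamSpec.symmetric(60.0))


@pytest.fixture
def random_disc_cloud(rng):
    """A moderate random disc cloud in front of the sonar."""
    n = 500
    centers = rng.uniform(-2.0, 2.0, (n, 3))
    centers[:, 0] = rng.uniform(1.2, 9.0, n)
    normals = rng.standard_normal((n, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return DiscSet(centers, normals, rng.uniform(0.005, 0.03, n))
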