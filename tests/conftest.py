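import numpy as np
import pytest

from anacurve import (LipConfig, PhantomSpec, estimate_breast_boundary,
                      estimate_lip_boundaries, make_lip_phantom,
                      make_torso_phantom, side_landmarks)


@pytest.fixture(scope="session")
def torso_phantom():
    spec = PhantomSpec.torso()
    cloud, landmarks, truth = make_torso_phantom(spec)
    return spec, cloud, landmarks, truth


@pytest.fixture(scope="session")
def breast_result(torso_phantom):
    _, cloud, landmarks, truth = torso_phantom
    lms = side_landmarks(landmarks, "r")
    return estimate_breast_boundary(cloud, lms), lms, truth


@pytest.fixture(scope="session")
def lip_phantom():
    spec = PhantomSpec.lip()
    cloud, landmarks, truth = make_lip_phantom(spec)
    return spec, cloud, landmarks, truth


@pytest.fixture(scope="session")
def lip_result(lip_phantom):
    _, cloud, _, truth = lip_phantom
    return estimate_lip_boundaries(cloud, LipConfig()), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
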