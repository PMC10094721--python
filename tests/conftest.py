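import numpy as np
import pytest
from hypothesis import settings

from loxtraj import synthetic as syn
from loxtraj.core import Frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dha_fragment():
    """All-Z hexaene chain with controlled span plane angles."""
    return syn.build_polyene_fragment(plane_angles={"C12": 75.0, "C9": 115.0})


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rigid_transform(rng):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return rot, t


def apply_rigid(frame: Frame, rot, t) -> Frame:
    return Frame(coords=frame.coords @ rot.T + t, frame_id=frame.frame_id)
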