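import numpy as np
import pytest

from cupversion.geometry import BeamGeometry, CupPose


@pytest.fixture
def ap_beam():
    return BeamGeometry(film="ap")


@pytest.fixture
def lat_beam():
    return BeamGeometry(film="crosstable_lateral")


@pytest.fixture
def pose_194():
    """Study-mean pose: anteversion 19.4 deg, inclination 45 deg, r 25."""
    return CupPose(anteversion_deg=19.4, inclination_deg=45.0, radius_mm=25.0)


def random_poses(n, seed=0, av_range=(5.0, 35.0), incl_range=(30.0, 55.0)):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            CupPose(
                anteversion_deg=float(rng.uniform(*av_range)),
                inclination_deg=float(rng.uniform(*incl_range)),
                radius_mm=float(rng.uniform(23.0, 30.0)),
                side=str(rng.choice(["left", "right"])),
            )
        )
    return out
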