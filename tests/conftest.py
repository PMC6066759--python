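import numpy as np
import pytest

from fluorosim.fixtures import RadiographSpec, make_radiograph
from fluorosim.geometry import AffineTransform2D
from fluorosim.simulator import Session


@pytest.fixture(scope="session")
def radiographs():
    """One synthetic AP and one CTL radiograph with annotations."""
    return {
        "AP": make_radiograph(RadiographSpec(plane="AP", seed=1)),
        "CTL": make_radiograph(RadiographSpec(plane="CTL", seed=2)),
    }


@pytest.fixture()
def replay_session(radiographs):
    """Open session with identity calibrations for scripted replay."""
    ident = AffineTransform2D.identity()
    return Session(
        radiographs=radiographs,
        calibrations={"AP": ident, "CTL": ident},
        start_time=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
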