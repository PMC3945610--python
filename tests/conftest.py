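import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from placefields.cue_model import CueParams
from placefields.geometry import CircularTrack, RectEnvironment
from placefields.synthetic import default_circular_track, default_linear_track


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def params():
    return CueParams(gamma=0.2)


@pytest.fixture
def linear_track() -> RectEnvironment:
    return default_linear_track()


@pytest.fixture
def circular_track() -> CircularTrack:
    return default_circular_track()


@pytest.fixture
def toy_track() -> CircularTrack:
    """Small three-object track for exhaustive-enumeration tests."""
    return CircularTrack(diameter_cm=60.0, track_width_cm=10.0,
                         object_arcs_cm=(40.0, 90.0, 150.0))
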