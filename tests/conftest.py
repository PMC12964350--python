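import numpy as np
import pytest

from larvatrack.features import Calibration
from larvatrack.synthetic import SceneSpec, simulate_scene


@pytest.fixture
def calibration():
    return Calibration(scale=0.1, fps=10.0)


@pytest.fixture(scope="session")
def small_scene():
    """A short collision-free three-animal scene used across modules."""
    spec = SceneSpec(
        n_objects=3, duration_s=30.0, seed=7, min_separation_mm=8.0
    )
    return simulate_scene(spec)
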