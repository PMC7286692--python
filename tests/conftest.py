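import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from facecontext import scenes, simulator  # noqa: E402

RF_CENTER = (1.0, -0.5)


@pytest.fixture(scope="session")
def small_session():
    """A compact simulated session shared across analysis tests: three
    intact and three occluded scenes on a 9x9 / 2-deg grid, two channels."""
    array = simulator.make_array(n_channels=2, center=RF_CENTER, seed=11)
    intact = scenes.make_scene_set("intact", 3, 5)
    occluded = scenes.make_scene_set("occluded", 3, 6)
    scene_list = intact + occluded
    protocol = scenes.make_protocol(9, 2.0, array.rf_center, scene_list,
                                    reps=5, seed=7)
    record = simulator.simulate_session(array, protocol, scene_list, seed=8)
    return {"array": array, "intact": intact, "occluded": occluded,
            "scenes": scene_list, "protocol": protocol, "record": record}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
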