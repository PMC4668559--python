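import numpy as np
import pytest

from mazeview import maze_task as mt
from mazeview.pipeline import make_fixtures


@pytest.fixture(scope="session")
def study_maps():
    """Three distracter-rich study maps (shared across the suite)."""
    return mt.generate_study_maps(seed=0)


@pytest.fixture(scope="session")
def study_trials(study_maps):
    """A full 5-session stimulus set on the shared maps."""
    return mt.generate_trial_set(study_maps, seed=1)


@pytest.fixture(scope="session")
def tiny_bundle():
    """1 participant, 2 sessions x 16 trials, 30-voxel ROIs, preprocessed."""
    return make_fixtures("tiny", seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_map():
    """A hand-built valid map: an outer corridor with a middle passage."""
    text = "\n".join([
        "#######",
        "#.....#",
        "#.###.#",
        "#.....#",
        "#.###.#",
        "#.....#",
        "#######",
    ])
    return mt.MazeMap.from_text(text, map_id=9)
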