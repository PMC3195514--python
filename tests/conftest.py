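import logging

import numpy as np
import pytest

import vastree as vt

logging.getLogger("vastree").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_spec():
    return vt.SceneSpec(seed=1)


@pytest.fixture(scope="session")
def scene_truth(default_spec):
    """One generated scene + ground truth shared across the session."""
    return vt.generate_scene(default_spec)


@pytest.fixture(scope="session")
def scene(scene_truth):
    return scene_truth[0]


@pytest.fixture(scope="session")
def truth(scene_truth):
    return scene_truth[1]


@pytest.fixture(scope="session")
def model(scene):
    return vt.build_tree_model(scene)


def straight_scene(length=60, row=50, col0=20, size=100):
    """A single horizontal centerline with a matching 5-px-wide mask."""
    cl = np.zeros((size, size), dtype=bool)
    cl[row, col0:col0 + length] = True
    mask = np.zeros((size, size), dtype=bool)
    mask[row - 2:row + 3, col0:col0 + length] = True
    return cl, mask
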