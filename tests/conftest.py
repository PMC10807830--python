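import numpy as np
import pytest

import confland as c


@pytest.fixture(scope="session")
def receptor():
    return c.generate_toy_receptor()


@pytest.fixture(scope="session")
def fshr():
    return c.load_receptor_geometry("fshr")


@pytest.fixture(scope="session")
def tm_idx(receptor, fshr):
    return c.resolve_selection(receptor, fshr.tm_selection)


@pytest.fixture(scope="session")
def ca_idx(receptor):
    return np.arange(receptor.n_atoms)


@pytest.fixture(scope="session")
def two_state(receptor):
    """Two-state labelled trajectory at the default study conditions,
    scaled to 400 frames for the unit suite."""
    spec = c.SyntheticSpec(n_frames=400, seed=7)
    traj, labels = c.generate_trajectory(receptor, spec)
    return spec, traj, labels


@pytest.fixture(scope="session")
def membrane():
    return c.generate_membrane_box(seed=3)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
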