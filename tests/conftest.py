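import numpy as np
import pytest

import agenorm as ag


@pytest.fixture(scope="session")
def small_spec():
    """Compact cohort spec used across tests: fast but structurally complete."""
    return ag.CohortSpec(n_cn=40, n_mci=15, grid_shape=(16, 16, 16), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return ag.generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel_size=(2.0, 2.0, 2.0)):
    return ag.GMVolume(np.asarray(data, dtype=float), voxel_size)


def constant_volume(value, shape=(8, 8, 8), voxel_size=(2.0, 2.0, 2.0)):
    return make_volume(np.full(shape, float(value)), voxel_size)
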