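"""Shared fixtures: small synthetic cohorts generated at test time."""
import numpy as np
import pytest

from fcdml.config import CohortConfig
from fcdml.synthetic import generate_cohort
from fcdml.types import BoldRun, BrainMask


TINY = dict(
    n_group_a=3,
    n_group_b=2,
    grid_shape=(10, 10, 10),
    n_frames=80,
    n_effect_clusters=0,
    motion_spike_rate=0.03,
    seed=11,
)

SMALL = dict(
    n_group_a=4,
    n_group_b=3,
    grid_shape=(14, 14, 14),
    n_frames=120,
    n_effect_clusters=1,
    hub_radius_vox=1.3,
    effect_size_d=1.5,
    seed=21,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """~300 mask voxels, no planted clusters; cheap generic input."""
    return generate_cohort(CohortConfig(**TINY))


@pytest.fixture(scope="session")
def small_cohort():
    """~800 mask voxels with one planted cluster pair."""
    return generate_cohort(CohortConfig(**SMALL))


@pytest.fixture()
def toy_run():
    """Deterministic 3x3x3x60 run with a constant-voxel corner."""
    rng = np.random.default_rng(5)
    data = rng.standard_normal((3, 3, 3, 60))
    data[0, 0, 0, :] = 7.0  # zero-variance voxel
    return BoldRun(data, 2.0, (3.0, 3.0, 3.0), np.eye(4), "toy")


@pytest.fixture()
def toy_mask():
    return BrainMask(np.ones((3, 3, 3), dtype=bool), np.eye(4))
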