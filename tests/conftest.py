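import numpy as np
import pytest

from predrep.envs import (
    ArmParams,
    WalkConfig,
    build_arena,
    build_card_world,
    generate_arm_trajectory,
    generate_card_trajectory,
    generate_spatial_trajectory,
)


@pytest.fixture(scope="session")
def card_world():
    return build_card_world(seed=0)


@pytest.fixture(scope="session")
def card_traj(card_world):
    return generate_card_trajectory(card_world, 5000, seed=1)


@pytest.fixture(scope="session")
def small_arena():
    return build_arena(size=8, smoothing_variance=2.0, seed=0)


@pytest.fixture(scope="session")
def arena_traj(small_arena):
    return generate_spatial_trajectory(small_arena, WalkConfig(), 3000, seed=2)


@pytest.fixture(scope="session")
def arm_traj():
    return generate_arm_trajectory(ArmParams(), 5000, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
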