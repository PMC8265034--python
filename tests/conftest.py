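import warnings

import numpy as np
import pytest

from mrflesion.dictionary import ParameterGrid, build_dictionary, build_grid
from mrflesion.phantom import PhantomConfig, generate_phantom
from mrflesion.schedule import default_schedule
from mrflesion.signal import simulate_baseline_stack

# test-scale phantom: reduced 64 x 64 matrix, lesions sized so some slices
# clear the augmentation threshold
TEST_PHANTOM_CONFIG = PhantomConfig(
    shape=(64, 64, 6), lesion_radius_vox=(2.5, 5.0), lesion_rate=6.0
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(TEST_PHANTOM_CONFIG, seed=7)


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(
        PhantomConfig(shape=(64, 64, 6), n_lesions=0), seed=3
    )


@pytest.fixture(scope="session")
def clean_stack(phantom, schedule):
    return simulate_baseline_stack(phantom, schedule)


@pytest.fixture(scope="session")
def coarse_dictionary(schedule):
    """Reduced dictionary (10% steps, 3 B1 values) for fast unit tests."""
    grid = ParameterGrid(
        t1_values=build_grid(300.0, 3500.0, 0.10),
        t2s_values=build_grid(10.0, 2500.0, 0.10),
        b1_values=np.array([0.8, 1.0, 1.2]),
    )
    return build_dictionary(schedule, grid)


@pytest.fixture(scope="session")
def default_dictionary(schedule):
    """The full default dictionary (5% steps, 9 B1 values)."""
    from mrflesion.dictionary import default_grid

    return build_dictionary(schedule, default_grid())


def make_phantom(seed, **overrides):
    cfg = PhantomConfig(
        **{**TEST_PHANTOM_CONFIG.__dict__, **overrides}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_phantom(cfg, seed=seed)
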