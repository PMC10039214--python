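"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from pelvreg import experiment
from pelvreg.phantom import PhantomConfig, generate_phantom_slice


@pytest.fixture(scope="session")
def phantom_slice():
    """One default 512 x 512 phantom slice with ground-truth masks."""
    return generate_phantom_slice(PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def small_pair():
    """One preprocessed 128 x 256 fixed/moving pair with masks."""
    pairs = experiment.make_synthetic_dataset(1, 1, image_shape=(128, 256),
                                              seed=11)
    return pairs[0]


@pytest.fixture(scope="session")
def cropped_slice(small_pair):
    """The preprocessed (cropped) fixed slice and its masks."""
    return small_pair.fixed, small_pair.fixed_masks


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
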