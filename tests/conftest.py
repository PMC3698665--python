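"""Shared fixtures: reference synthetic image set and learned statistics.

The reference conditions mirror the study setup: five 300x300 images at
target blackness 0.3755 with correlation length 6 px, learned with pair
gaps up to 8 px (the largest interpolation gap).
"""

import numpy as np
import pytest

from cytocrowd.fixtures import FixtureSpec, make_tem_like
from cytocrowd.imaging import binarize, learn_stats


REF_SPEC = FixtureSpec(target_blackness=0.3755, corr_length_px=6.0,
                       size=300, n_images=5, noise_sd=25.0, seed=1)


@pytest.fixture(scope="session")
def ref_images():
    return make_tem_like(REF_SPEC)


@pytest.fixture(scope="session")
def ref_binary(ref_images):
    return [binarize(im) for im in ref_images]


@pytest.fixture(scope="session")
def ref_stats(ref_binary):
    return learn_stats(ref_binary, max_gap=8)


@pytest.fixture(scope="session")
def matched_volume_64(ref_stats):
    """A 64^3 matched volume for simulation-level tests."""
    from cytocrowd.volumegen import GenConfig, generate_volume

    return generate_volume(ref_stats, size=64, cfg=GenConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
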