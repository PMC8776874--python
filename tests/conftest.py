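import numpy as np
import pytest

import gliohab as gh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small phantom spec for fast structural tests (not the study defaults)."""
    return gh.HabitatSpec(shape=(24, 24, 24))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return gh.generate_cohort(tiny_spec, n_mutant=4, n_wildtype=4, seed=7)


def make_zspec(ratio, offsets=None, s0_value=100.0, mask=None):
    """Wrap a normalized-ratio array (x, y, z, n_offsets) as a ZSpectrumVolume."""
    ratio = np.asarray(ratio, dtype=float)
    offsets = gh.default_offsets() if offsets is None else np.asarray(offsets)
    shape = ratio.shape[:-1]
    mask = np.ones(shape, dtype=bool) if mask is None else mask
    return gh.ZSpectrumVolume(ratio * s0_value, offsets,
                              np.full(shape, s0_value), mask)
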