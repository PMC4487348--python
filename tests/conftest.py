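import numpy as np
import pytest

from peakfill import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(20150221)


@pytest.fixture
def small_spectra(rng):
    """Three random spectra on a 120-channel m/z axis."""
    axis = np.linspace(100.0, 900.0, 120)
    y = 10.0 + rng.normal(0, 1, (3, 120)).cumsum(axis=1) * 0.1
    y += rng.uniform(0, 5, (3, 120))
    return SpectraSet(axis, y)
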