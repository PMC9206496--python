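import numpy as np
import pytest

from glossprobe import stimuli, threshold


@pytest.fixture(scope="session")
def small_catalog():
    """12 scenes x 15 conditions at 64x64 (180 stimuli)."""
    return stimuli.build_catalog(12, size=64, seed=11)


@pytest.fixture(scope="session")
def fitted_threshold(small_catalog):
    return threshold.fit_threshold(
        [r.image for r in small_catalog],
        [r.components.specular for r in small_catalog],
        max_pixels=60_000, seed=0)


@pytest.fixture(scope="session")
def plain_records(small_catalog):
    return [r for r in small_catalog if r.condition == "plain"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
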