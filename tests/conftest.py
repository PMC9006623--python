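import numpy as np
import pytest

from roaflow import DffStack, MovieStack, SynthConfig, generate_movie


@pytest.fixture
def constant_movie():
    """3-frame 4x4 stack, all pixels 100."""
    return MovieStack(
        data=np.full((3, 4, 4), 100.0), pixel_size=1.0, frame_interval=1.0
    )


def make_dff(data, pixel_size=1.0, frame_interval=1.0, valid=None):
    data = np.asarray(data, dtype=float)
    if valid is None:
        valid = np.ones(data.shape[1:], dtype=bool)
    return DffStack(
        data=data, valid_mask=valid, pixel_size=pixel_size, frame_interval=frame_interval
    )


@pytest.fixture(scope="session")
def small_astro():
    """A compact noisy movie with implanted regions/events and its truth."""
    cfg = SynthConfig(shape=(150, 64, 64), n_regions=5, area_range=(10.0, 60.0),
                      rng_seed=7)
    movie, truth = generate_movie(cfg)
    return cfg, movie, truth
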