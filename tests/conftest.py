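import numpy as np
import pytest

from ratioquant import SyntheticSampleSpec


@pytest.fixture
def small_spec():
    """A quick-to-render sample spec used across tests."""
    return SyntheticSampleSpec(
        sample_id="s1",
        group_label="g",
        n_images=2,
        cells_per_image=5,
        true_mean_ratio=0.6,
        between_cell_sd=0.05,
        red_mean_level=1000.0,
        red_cell_cv=0.1,
        background_level=0.0,
        pixel_noise_sd=20.0,
        image_shape=(96, 96),
        cell_radius_range=(4.0, 8.0),
        seed=7,
    )


@pytest.fixture
def noise_free_spec(small_spec):
    """Zero-noise, zero-background variant for exactness checks."""
    return small_spec.replace(pixel_noise_sd=0.0, background_level=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
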