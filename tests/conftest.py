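import numpy as np
import pytest

from ctc_origin import SceneConfig, default_frequency_table


@pytest.fixture(scope="session")
def table():
    return default_frequency_table()


@pytest.fixture
def small_scene_config():
    """A quick-to-render scene: 12 tumor cells + 5 leukocytes on 400x400."""
    return SceneConfig(
        image_height=400,
        image_width=400,
        n_tumor_cells=12,
        n_leukocytes=5,
        tissue_type="breast",
        sex="female",
        seed=42,
    )


@pytest.fixture
def noise_free_config():
    """Noise-free, non-overlapping, organic-dye scene: segmentation and
    positivity must be exact on it."""
    return SceneConfig(
        image_height=400,
        image_width=400,
        n_tumor_cells=12,
        n_leukocytes=5,
        tissue_type="breast",
        sex="female",
        noise_sd=0.0,
        clump_probability=0.0,
        mode="dylight",
        foreground_log_sd=0.1,
        seed=9,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
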