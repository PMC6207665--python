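import numpy as np
import pytest

from fibrostage.preprocess import ProcessedImage
from fibrostage.synthetic import StageParams, default_stage_table, generate_image


@pytest.fixture(scope="session")
def stage_table():
    return default_stage_table()


@pytest.fixture(scope="session")
def single_fiber_params():
    """Noise-free single-fiber parameters for ground-truth recovery."""
    return StageParams(stage=0, n_fibers=1, length_mean=60.0, length_sd=0.0,
                       width_mean=3.0, width_sd=0.0, bridging_prob=0.0,
                       septa_count=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_phantom(stage_table):
    """One deterministic mid-stage phantom at desk scale."""
    img, gt = generate_image(stage_table[2], seed=7, shape=(256, 256))
    return img, gt


def make_processed(mask, tissue=None, enhanced=None):
    """Assemble a ProcessedImage directly from arrays (for unit tests)."""
    mask = np.asarray(mask, dtype=bool)
    if tissue is None:
        tissue = np.ones_like(mask)
    if enhanced is None:
        enhanced = np.where(mask, 200.0, 20.0)
    return ProcessedImage(enhanced=np.asarray(enhanced, dtype=float),
                          collagen_mask=mask,
                          tissue_mask=np.asarray(tissue, dtype=bool),
                          params={})


@pytest.fixture
def processed_factory():
    return make_processed
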