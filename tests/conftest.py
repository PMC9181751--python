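import numpy as np
import pytest

from choroidnet import BScanImage, CropConfig, PhantomConfig, generate_bscan


@pytest.fixture
def easy_phantom_config() -> PhantomConfig:
    """Small, low-noise phantom used across the suite."""
    return PhantomConfig(height=128, width=256, channels=1,
                         thickness_range=(20, 100), bm_depth_range=(8, 16),
                         boundary_amplitude=3.0, speckle_sigma=0.02,
                         vessel_contrast=0.05)


@pytest.fixture
def noiseless_constant_config() -> PhantomConfig:
    """Constant 50 px thickness, no undulation, no noise."""
    return PhantomConfig(height=128, width=256, channels=1,
                         thickness_range=(50, 50), bm_depth_range=(20, 30),
                         boundary_amplitude=0.0, speckle_sigma=0.0,
                         vessel_contrast=0.0)


@pytest.fixture
def small_scan(easy_phantom_config):
    return generate_bscan(easy_phantom_config, seed=3)


@pytest.fixture
def small_crop_config() -> CropConfig:
    return CropConfig(k_segments=4, patch_height=64, vertical_stride=10)


def random_image(rng: np.random.Generator, height: int, width: int) -> BScanImage:
    return BScanImage(pixels=rng.uniform(size=(height, width)))
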