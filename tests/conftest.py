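import numpy as np
import pytest

from biliscreen import (
    ChannelEffectModel,
    CohortConfig,
    SkinImage,
    default_effect_model,
    sample_cohort,
)


@pytest.fixture(scope="session")
def default_effects():
    return default_effect_model()


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(CohortConfig(n_subjects=12, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_image():
    """Uniform 16x16 patch at (200, 180, 160)."""
    px = np.empty((16, 16, 3), dtype=np.uint8)
    px[:, :, 0] = 200
    px[:, :, 1] = 180
    px[:, :, 2] = 160
    return SkinImage(px)


def noiseless_effects(alpha=(200.0, 180.0, 160.0)):
    return ChannelEffectModel(alpha=alpha, tsb_slope=(0.0, 0.0, 0.0))
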