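import numpy as np
import pytest

from derma_radiomics import GLCMParams, SyntheticConfig
from derma_radiomics.image_prep import MaskedLevelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20230926)


@pytest.fixture
def tiny_config():
    """A reduced cohort whose images are small enough for fast tests.

    Same statistical structure as the full-scale defaults; only the
    image geometry and field scales shrink.
    """
    return SyntheticConfig(
        n_patients=4,
        image_height=64,
        image_width=64,
        correlation_length=3.0,
        blotch_correlation_length=8.0,
        seed=7,
    )


@pytest.fixture
def tiny_roi_radius():
    return 24.0


@pytest.fixture
def small_params():
    return GLCMParams(n_levels=8)


def random_masked_grid(rng, max_size=12, n_levels=8, circular=False):
    """A random small level grid with a random or circular mask."""
    h = int(rng.integers(4, max_size + 1))
    w = int(rng.integers(4, max_size + 1))
    levels = rng.integers(1, n_levels + 1, size=(h, w))
    if circular:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        radius = min(h, w) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    else:
        mask = rng.random((h, w)) < 0.8
    levels = levels * mask  # 0 sentinel outside the mask
    return MaskedLevelGrid(levels=levels, mask=mask, n_levels=n_levels)
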