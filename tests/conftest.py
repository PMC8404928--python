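import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_blob(rng, size=64, smooth=3.0, q=0.65, clear_border=True):
    """Smooth random foreground mask (Gaussian-filtered noise, thresholded)."""
    f = ndimage.gaussian_filter(rng.normal(size=(size, size)), smooth)
    mask = f > np.quantile(f, q)
    if clear_border:
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return mask


def random_mask(rng, size=16, p=0.5):
    """Unstructured random boolean mask with at least one background pixel."""
    mask = rng.random((size, size)) < p
    mask[0, 0] = False
    return mask
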