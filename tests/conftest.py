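import numpy as np
import pytest
import warnings

# registration emits convergence warnings on marginal frames; tests assert
# on returned flags instead
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_image(rng):
    """Reproducible image with broad-band texture (for exact-shift tests)."""
    a = rng.normal(size=(64, 64)) + 5
    return np.cumsum(np.cumsum(a, axis=0), axis=1) % 7


@pytest.fixture()
def smooth_image(rng):
    """Band-limited smooth image resembling microscopy content."""
    from scipy import ndimage
    return ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)


def _fourier_shift_image(img, dx, dy):
    from scipy import ndimage
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img),
                                                      (dy, dx))))


@pytest.fixture()
def fourier_shift_image():
    """Exact band-limited translation (the noise-free shift oracle)."""
    return _fourier_shift_image
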