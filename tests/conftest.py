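import numpy as np
import pytest

from drusenkit import Druse, FundusImage, SimImageParams, generate_fundus_pair


@pytest.fixture
def flat_blob_pair():
    """Two well-separated circular drusen on a flat background, no noise."""
    params = SimImageParams(
        shape=(128, 128),
        scale_um_per_px=25.0,
        background_coeffs=((50.0, 0.0, 0.0, 0.0, 0.0, 0.0),),
        noise_sd=0.0,
        drusen=(
            Druse((40.0, 40.0), (200.0, 200.0), 100.0),
            Druse((90.0, 90.0), (150.0, 150.0), 100.0),
        ),
    )
    baseline, final, truth = generate_fundus_pair(params, seed=0)
    return params, baseline, truth


@pytest.fixture
def quadratic_image():
    """An image that is exactly one global quadratic background, no drusen."""
    coeffs = (100.0, 8.0, -5.0, -20.0, 3.0, -12.0)
    params = SimImageParams(
        shape=(96, 96),
        scale_um_per_px=25.0,
        background_coeffs=(coeffs,),
        noise_sd=0.0,
    )
    img, _, truth = generate_fundus_pair(params, seed=0)
    return img, np.asarray(coeffs), truth


def constant_image(value=7.0, shape=(32, 32), scale=10.0):
    return FundusImage(np.full(shape, value), scale, (shape[0] / 2, shape[1] / 2))
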