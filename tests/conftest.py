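import numpy as np
import pytest

from histograph import ImageRecord, TextureSpec, generate_texture_image


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def blob_image():
    return generate_texture_image(
        TextureSpec(class_name="blobs", motif="blobs", seed=5), 128, 128
    )


@pytest.fixture()
def fibre_image():
    return generate_texture_image(
        TextureSpec(
            class_name="fibres", motif="fibres", motif_scale=6.0,
            orientation=30.0, seed=5,
        ),
        128,
        128,
    )


@pytest.fixture()
def quadrant_image():
    """Four uniform intensity quadrants: a trivially correct
    superpixel ground truth."""
    img = np.zeros((64, 64))
    img[:32, :32] = 0.2
    img[:32, 32:] = 0.4
    img[32:, :32] = 0.6
    img[32:, 32:] = 0.8
    truth = np.zeros((64, 64), dtype=int)
    truth[:32, 32:] = 1
    truth[32:, :32] = 2
    truth[32:, 32:] = 3
    return ImageRecord(id="quadrants", pixels=img), truth
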