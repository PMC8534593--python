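import numpy as np
import pytest

from busecho import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def benign_params():
    """Smooth elliptical lesion, the reference geometry used across tests."""
    return phantom.PhantomParams(
        image_size=(256, 256),
        class_label=phantom.BENIGN,
        lesion_center=(128.0, 128.0),
        lesion_axes=(20.0, 12.0),
        boundary_irregularity=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 3-per-class phantom dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = phantom.generate_dataset(3, seed=5, out_dir=out, image_size=(64, 64))
    return manifest, out
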