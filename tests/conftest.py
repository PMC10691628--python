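import numpy as np
import pytest

from pisunet.phantom import generate_dataset
from pisunet.preprocessing import preprocess_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """9 synthetic patients, 2 slices each, both lesion classes, 64px slices."""
    root = tmp_path_factory.mktemp("phantoms")
    return generate_dataset(
        n_patients=9, slices_per_patient=(2, 2), class_mix=0.5,
        out_dir=root, seed=11, image_size=64,
    )


@pytest.fixture(scope="session")
def preprocessed_dataset(small_dataset, tmp_path_factory):
    """The small dataset ROI-cropped, resized to 64 and min-max normalised."""
    out = tmp_path_factory.mktemp("preprocessed")
    return preprocess_dataset(small_dataset, out, target_size=64, margin_frac=0.25)
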