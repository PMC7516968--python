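import numpy as np
import pytest

from dermofuse import SyntheticLesionSpec, make_lesion_image, preprocess


@pytest.fixture(scope="session")
def default_image():
    """One deterministic synthetic lesion image with ground truth."""
    spec = SyntheticLesionSpec(seed=11, n_colors=2, hair_count=0, asymmetry_level=0.1)
    return make_lesion_image(spec)


@pytest.fixture(scope="session")
def lesion_roi(default_image):
    rgb, _, _ = default_image
    return preprocess(rgb, sigma=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
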