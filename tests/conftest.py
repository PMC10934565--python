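import numpy as np
import pytest

from cxrdiff import phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_pair():
    """A deterministic 128px pair with one new lesion and mild noise."""
    spec_rng = np.random.default_rng(7)
    spec = phantom.random_pair_spec(spec_rng, image_size=128,
                                    noise_sigma=0.01, max_deformation=2.5,
                                    lesion_prob=0.0, new_lesion_prob=1.0)
    pre, post, truth = phantom.generate_pair(spec)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def identity_pair():
    """Pre == post exactly (no deformation, lesions, gain or noise)."""
    spec = phantom.PhantomSpec(image_size=128, noise_sigma=0.0,
                               edge_blur_sigma=1.0, box_allowance=3)
    pre, post, truth = phantom.generate_pair(spec)
    return spec, pre, post, truth
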