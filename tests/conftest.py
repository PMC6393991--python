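import numpy as np
import pytest

from ecmorph import FixtureSpec, generate_islet_image


@pytest.fixture(scope="session")
def default_fixture():
    """One typical synthetic ROI (15% collagen, 20% white space), shared
    read-only across tests: (spec, image, collagen_mask, tissue_mask)."""
    spec = FixtureSpec(seed=7, target_collagen_fraction=0.15,
                       white_space_fraction=0.2)
    img, collagen, tissue = generate_islet_image(spec)
    return spec, img, collagen, tissue


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
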