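import logging

import numpy as np
import pytest

from caliperase import annotate, phantom

logging.getLogger("caliperase").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset() -> phantom.PhantomDataset:
    """A small seeded phantom dataset shared across tests."""
    cfg = phantom.PhantomConfig(n_train=6, n_test=3)
    return phantom.render_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def annotated_fixture(small_dataset):
    """One phantom with calipers burned at every nodule."""
    item = small_dataset.items[0]
    return annotate.annotate_phantom(item.image, item.nodules, seed=21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
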