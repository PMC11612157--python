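import numpy as np
import pytest

from optopattern import fixtures as fx
from optopattern import segmentation as seg


@pytest.fixture(scope="session")
def trained_classifier():
    """Region classifier fitted on disk-vs-distractor training fixtures."""
    train = [
        fx.disk_fixture(n_disks=20, n_distractors=12, seed=s, shape=(320, 320))
        for s in (11, 12)
    ]
    return seg.train_region_classifier(train, seed=0)


@pytest.fixture(scope="session")
def eval_fixture():
    """The standard 30-disk evaluation image with ground truth."""
    return fx.disk_fixture(n_disks=30, shape=(320, 320), snr=6.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
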