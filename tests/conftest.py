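import warnings

import numpy as np
import pytest

from emofuse.simulate import SimConfig, generate_epochs


@pytest.fixture(scope="session")
def small_epochs():
    """A small labelled epoch set (short windows; entropy warnings silenced)."""
    cfg = SimConfig(n_channels=8, n_samples=1024, n_trials_per_class=5, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_epochs(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
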