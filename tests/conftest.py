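import numpy as np
import pytest

import lavaset as lv


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def block_dataset():
    """40 samples x 20 features with two informative correlated blocks.

    Features 3-7 and 12-16 each share a latent class signal plus noise; the
    rest are pure noise.  Returns (X, y).
    """
    g = np.random.default_rng(7)
    n_per = 20
    y = np.repeat([0, 1], n_per)
    X = g.normal(0, 1.0, size=(2 * n_per, 20))
    signal = np.where(y == 1, 2.0, 0.0) + g.normal(0, 0.4, size=2 * n_per)
    for block in (range(3, 8), range(12, 17)):
        for f in block:
            X[:, f] += signal + g.normal(0, 0.3, size=2 * n_per)
    return X, y


@pytest.fixture(scope="session")
def small_forest(block_dataset):
    """A 7-tree forest with k=2 spectral neighbourhoods on the block data."""
    X, y = block_dataset
    nmap = lv.from_spectral_axis(np.arange(X.shape[1], dtype=float), 2)
    cfg = lv.FitConfig(n_trees=7, k_neighbors=2, rng_seed=11)
    return lv.fit_forest(X, y, nmap, cfg), X, y
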