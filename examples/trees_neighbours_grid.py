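"""Grid search over the two main hyperparameters: trees and neighbours.

All combinations share one fixed stratified 80/20 split and identical
per-repeat bootstrap seeds, so differences in the table reflect the
hyperparameters, not sampling luck.
"""

import numpy as np

import lavaset as lv

cfg = lv.default_spectrum_config(n_features=300, n_samples_per_class=40,
                                 rng_seed=5)
X, y, _ = lv.simulate_spectra(cfg)

table = lv.grid_search(
    X, y, np.arange(X.shape[1], dtype=float),
    tree_grid=[25, 100], neighbor_grid=[0, 5, 15],
    n_repeats=2, seed=5)
print(table[["n_trees", "k", "accuracy_mean", "accuracy_sd", "f1_mean"]]
      .to_string(index=False))
# each row is the mean +/- sd of held-out metrics over the repeats; k=0 is
# the classic random-forest baseline, larger k averages more neighbours into
# every split's latent variable.
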