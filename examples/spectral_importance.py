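"""Recover whole multiplets from a simulated NMR-like spectral cohort.

Simulates two classes of 1D spectra that differ in the intensity of four
multiplets, fits a latent-variable forest whose splits use each candidate
feature's 11-point spectral neighbourhood (k=10), and scores how completely
the importance output covers the true peak points.
"""

import numpy as np

import lavaset as lv

cfg = lv.default_spectrum_config(n_features=500, n_samples_per_class=50,
                                 rng_seed=7)
X, y, truth = lv.simulate_spectra(cfg)
print(f"simulated {X.shape[0]} spectra x {X.shape[1]} points, "
      f"{truth.mask.sum()} discriminative peak points")

nmap = lv.from_spectral_axis(np.arange(X.shape[1], dtype=float), k=10)
forest = lv.fit_forest(X, y, nmap,
                       lv.FitConfig(n_trees=100, k_neighbors=10, rng_seed=7))

report = forest.importance_report()
cov = lv.peak_coverage(report.normalized_gini, truth, k=10)
print(f"peak coverage: precision={cov.precision:.3f} recall={cov.recall:.3f} "
      f"f1={cov.f1:.3f}")
# recall near 1 means the forest assigned importance to (almost) every point
# of every discriminative multiplet, not just isolated maxima; precision
# counts the k flanking off-peak points per multiplet as the negatives.

top = np.argsort(report.importance)[::-1][:5]
print("top features by final importance:", top.tolist())
print("their multiplet membership    :", truth.mask[top].tolist())
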