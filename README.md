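# lavaset

Latent-variable stochastic ensembles of trees for datasets whose features are
spatially, spectrally, or temporally **correlated** — ¹H-NMR spectra,
multi-lead ECG/VCG traces, values on anatomical meshes.

Classic random forests split every node on a single feature. On correlated
data this concentrates feature importance on isolated points: a forest may
flag three scattered points of a 40-point metabolite multiplet and miss the
rest, and a single high-variance noisy feature can outrank genuine signal.
`lavaset` implements the LAVASET approach: every split is made on a *latent
variable* summarising a candidate feature's local neighbourhood, and the
split's quality is credited back to the whole neighbourhood — so correlated
features rise and fall together.

## The method

For a candidate feature of interest (FOI) at a tree node, let
𝒩(FOI, k) be the indices of the FOI plus its k nearest features under a
user-chosen distance structure, and let `FOIn` be the node's sample ×
(k+1) sub-matrix over those features, autoscaled column-wise (mean 0,
variance 1). From the singular value decomposition

    FOIn = U Σ Vᵀ

the node's latent variable is the first principal direction: each sample's
score is its projection on **v₁** (proportional to the first left singular
vector **u₁**), and the loadings are **L** = σ₁ **v₁**. The best split is
the classic Gini search over the latent scores: impurity G = 1 − Σ_c p_c²,
gain ΔG = G(parent) − (n_L/n)·G(left) − (n_R/n)·G(right), thresholds at
midpoints between consecutive distinct scores. Trees grow to pure leaves as
in CART; the forest bootstraps samples per tree and predicts by majority
vote. With k = 0 the method reduces exactly to a single-feature Gini CART
ensemble.

Three per-feature accumulators are kept across all trees — how often a
feature was an **evaluated** candidate, how often it was **selected** as the
winning FOI, and its accumulated **gini** share: each winning split's gain is
distributed over its neighbourhood members with weights |L_m| / Σ_j |L_j|,
conserving the gain exactly. The final score is

    importance(i) = gini(i) / Σ_f gini(f)  ×  selected(i) / evaluated(i)

and the gain-conserving `gini` / `normalized_gini` columns carry the full
neighbourhood-resolved signal (a neighbour that was never itself the winning
FOI has positive `gini` but zero final score; peak-coverage evaluation
therefore thresholds `normalized_gini`).

Neighbourhoods come from any of four distance structures:

| mode | input | typical use |
|---|---|---|
| `from_distance_matrix` | feature × feature distances (CSV) | anything precomputed |
| `from_spectral_axis` | monotone 1D axis (e.g. ppm) | NMR / 1D spectra |
| `from_cyclic_multichannel` | channels × cyclic time grid | VCG / cardiac cycles |
| `from_spatial_consensus` | per-sample 3D coordinates | mesh points; keeps neighbours stable in >½ of samples |

## Worked example

`examples/spectral_importance.py` simulates a two-class spectral cohort
(four discriminative multiplets among distractor peaks), fits a 100-tree
forest with 11-point spectral neighbourhoods, and scores peak coverage:

```
simulated 100 spectra x 500 points, 82 discriminative peak points
peak coverage: precision=0.726 recall=1.000 f1=0.841
top features by final importance: [55, 56, 59, 54, 57]
their multiplet membership    : [True, True, True, True, True]
```

Recall 1.0 means *every* point of every discriminative multiplet received
importance — the claim that motivates the method; precision counts the k
flanking off-peak points per multiplet as designated negatives, so it is
bounded by how far neighbourhood spill reaches past the peak edges. The
other examples cover cyclic multi-channel traces, consensus neighbourhoods
on jittered 3D point clouds, and the trees × neighbours grid search.

A thin CLI wraps the same functions:

```sh
lavaset simulate spectra --seed 3 --out sim/
lavaset fit --data sim/data.csv --labels-col label --mode spectral \
        --neighbors 10 --trees 100 --seed 3 --out run/
lavaset evaluate --importance run/importance.csv --truth sim/truth.csv --k 10
```

## Scope

Binary/multi-class classification only: no regression, missing-value
surrogates, boosting, or out-of-bag scoring. See `docs/methods.md` for the
model's assumptions, parameter conventions, and known limitations.
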