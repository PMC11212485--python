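# Methods

## Model

`lavaset` fits an ensemble of binary decision trees in which every node
split is *oblique within a local neighbourhood*. At a node holding samples
S, each of `max_features` candidate features (FOIs, drawn uniformly without
replacement from all features, fresh at every node) anchors a neighbourhood
𝒩(FOI, k): the FOI plus its k nearest features under the chosen distance
structure, computed once before fitting and shared by all trees. The node's
sub-matrix over 𝒩 is autoscaled per column — mean 0 and unit *population*
variance over the samples at that node, recomputed at every node — and
decomposed as Z = U Σ Vᵀ. The candidate's latent variable assigns sample i
the score (Z v₁)ᵢ = σ₁ u₁ᵢ; the unit-norm v₁ is stored so unseen samples
project as (x − center)/scale · v₁. Loadings L = σ₁ v₁ equal the covariance
pattern between the latent variable and the scaled members (identically
u₁ᵀZ). The split threshold is the Gini-optimal midpoint between consecutive
distinct latent scores, `score ≤ threshold` going left. Growth recurses to
pure leaves (or `min_samples_split` / `max_depth`); an unsplittable node
becomes a majority leaf. Forests bootstrap n samples with replacement per
tree and predict by majority vote, ties to the class declared first in the
training labels.

Assumptions: discriminative signal is shared by features that are *close*
under the supplied distance structure; neighbourhood size k is meaningful a
priori (spectral line width, temporal window, spatial patch) and is the one
hyperparameter without a safe universal default. When features are truly
uncorrelated, k = 0 reduces every mechanism to a classic Gini CART forest —
scaling is monotone per feature, so optimal partitions coincide with CART's.

## Importance

Three accumulators per feature across the forest: `evaluated` (+1 per node
where the feature was a candidate FOI), `selected` (+1 when it won the
split as FOI), and `gini`, the accumulated share of winning-split gains.
Each winning split's gain is distributed over its neighbourhood members with
weights |L_m| / Σ_j |L_j|: non-negative, summing to the gain exactly, so
Σ_f gini(f) equals the total impurity decrease of the forest to accumulation
precision. Final score: `normalized_gini × selected/evaluated` (features
never evaluated score 0); `gini/selected` is reported as an auxiliary
column.

Two interpretation choices were genuinely open:

* **Loading weights.** Loadings are signed; gain shares use their absolute
  values normalized to sum one. Signed weights would let importance cancel
  across anti-correlated members and break gain conservation.
* **Which column expresses neighbourhood spill.** `selected` counts only the
  winning FOI, so the *final* score is zero for a member that never won as
  FOI itself, however often its neighbourhood won. The neighbourhood-level
  claim — every member of a winning neighbourhood carries importance —
  lives in the gain-conserving `gini`/`normalized_gini` columns, and the
  peak-coverage evaluation (and the CLI `evaluate` default) thresholds
  `normalized_gini > 0`. The final product score remains the headline
  per-feature ranking.

## Neighbourhood constructions

All modes list the FOI first and break distance ties toward the lower
feature index; k counts neighbours excluding the FOI.

* *Distance matrix*: rows sorted stably; matrix must be symmetric within
  1e-8 with zero diagonal.
* *Spectral axis*: two-pointer sweep over a strictly monotone axis;
  provably identical to the materialized distance matrix.
* *Cyclic multi-channel*: features indexed channel-major; the neighbourhood
  of (channel c, time i) is every channel at times i, i±1, …, i±steps
  modulo the cycle length (first and last time points adjacent), giving
  n_channels·(2·steps+1) members; windows wider than the cycle are
  rejected.
* *Spatial consensus*: per-sample Euclidean k-NN; points kept only if they
  are neighbours in strictly more than `consensus_fraction` (default 0.5)
  of samples, ordered by appearance frequency, then mean within-sample
  rank, then index, truncated to the k best-supported. One consensus pass
  is performed (no iteration to a fixed point); features may keep fewer
  than k survivors, which are used as-is with a warning.

## Randomness and determinism

All randomness flows from one integer seed through `SeedSequence` spawning:
per-tree child streams drive that tree's bootstrap and its per-node
candidate draws, so forests are bit-identical for a given seed regardless of
the worker count (`n_jobs`), and growing more trees never perturbs earlier
trees. Ledgers are merged in tree order, making floating-point sums
reproducible. Model files are canonical JSON (sorted keys, shortest
round-trip floats), so identical fits serialize to identical bytes.

## Numerical choices

* Gain comparisons use an absolute tie tolerance of 1e-12: Gini gains are
  ratios of small integers, and distinct gains at realistic node sizes
  differ by far more, so the tolerance routes mathematically tied candidates
  to the deterministic rules (lower FOI index; lower threshold) rather than
  to last-ulp noise.
* Latent sign is fixed so the largest-|loading| member is positive —
  needed only for reproducible serialization; partitions are sign-invariant.
* Constant columns at a node get scale divisor 1 (centred zeros); a fully
  constant sub-matrix disqualifies the candidate. Split thresholds that
  collapse onto a sample score under float rounding fall back to the left
  sample's score; a candidate whose threshold empties a child is discarded.
* Splits require strictly positive gain; otherwise the node becomes a leaf.

## Synthetic benchmarks

The spectral generator emulates the structure the method targets rather than
NMR physics: each multiplet is a cluster of Lorentzian (optionally Gaussian)
sub-peaks; a sample is the sum of its multiplet profiles, a per-sample
per-multiplet amplitude scatter (concentration-like, shared by all points of
a multiplet), optional centre jitter, and i.i.d. baseline noise. Class 1
scales designated multiplets by a `class_effect` factor. The ground-truth
mask marks points within one width of any discriminative sub-peak centre.

The default benchmark places four discriminative multiplets proportionally
at 11.85%, 36.6%, 58.0% and 75.45% of a 1000-point axis — the positions of
ethanol's two multiplets and uracil's two doublets on a 10-ppm scale — each
a triplet of width-10 sub-peaks spaced 10 points (41-point masks), plus
three non-discriminative distractor multiplets. The regime `class_effect
1.6, baseline_sd 0.3, amplitude_sd 0.1` was chosen jointly against three
requirements a realistic cohort satisfies: adjacent in-peak points correlate
above 0.8 across samples (between-class plus concentration variance
dominating baseline noise), classes are separable but individual points are
not clean (trees of nontrivial depth), and masks are wide relative to the
default k = 10 neighbourhood, as metabolite peaks are relative to practical
neighbour counts.

What passing on this generator does *not* show: robustness to peak shifts
larger than a line width, baseline distortions, phasing artefacts, overlap
of discriminative and distractor peaks, or class imbalance — none of which
the generator produces. The cyclic generator (shared jittered deflection +
windowed class bump) and the point-cloud generator (jittered template cloud,
smooth field, contiguous affected region) are likewise structural stand-ins,
not physiological models.

The evaluation suite scores *peak coverage*: positives are the mask points;
per contiguous peak, ⌈k/2⌉ points immediately left and ⌊k/2⌋ immediately
right are designated true negatives (flanks are exactly where neighbourhood
spill would create false positives); a point is called positive iff its
importance exceeds zero, so the measure ignores monotone rescaling.
Overlapping flank regions are merged with a warning. Problem sizes
throughout the test suite and the acceptance script (200 samples × 1000
features, 100 trees) are the package's default benchmark scale; oracle
comparisons (exhaustive CART, rational-arithmetic split enumeration,
eigendecomposition, brute-force neighbourhood constructions) run on small
instances where exhaustion is exact.

## Known limitations

* `evaluated` counts accrue per node visit; with few trees the
  selected/evaluated ratio is noisy for rarely drawn features.
* Spatial consensus is a single pass; an iterated fixed-point variant could
  retain different neighbour sets.
* Per-FOI neighbourhood sizes vary implicitly only in spatial mode; the
  other modes use a global k.
* No missing-value handling, regression targets, class weights, or
  out-of-bag estimates; training/evaluation splits are the caller's job
  (the grid search fixes one stratified 80/20 split).
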