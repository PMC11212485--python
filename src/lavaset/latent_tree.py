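"""Growing a single latent-variable decision tree.

Instead of splitting on one feature at a time, each node picks a candidate
feature of interest (FOI), gathers its neighbourhood sub-matrix, autoscales it
over the samples present at the node, and extracts the first singular
direction: the latent variable actually split on is the projection of the
scaled sub-matrix onto the first right singular vector.  The split threshold
is then found by the classic Gini search over the latent scores, and the tree
recurses to pure leaves exactly as CART does.

With ``k = 0`` (single-member neighbourhoods) the latent score is an affine
increasing transform of the raw feature, so the tree reduces to an ordinary
Gini CART over the sampled candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .importance import TreeLedger

__all__ = [
    "FitConfig",
    "LatentSplitRecord",
    "TreeNode",
    "gini_index",
    "gini_gain",
    "compute_latent",
    "best_split",
    "grow_tree",
    "predict_tree",
]

_SCALE_EPS = 1e-12

# Gini gains are ratios of small integers; distinct gains on node sizes in the
# hundreds differ by far more than this, so treating differences below it as
# ties lets the deterministic lower-index/lower-threshold rules win instead of
# last-ulp float noise.
GAIN_TIE_TOL = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters for one forest fit.

    ``max_features`` is the number of candidate FOIs drawn (without
    replacement) at every node; the default ``"sqrt"`` resolves to
    ceil(sqrt(n_features)).  ``k_neighbors`` is the nominal neighbour count of
    the neighbourhood map (excluding the FOI).
    """

    n_trees: int = 100
    k_neighbors: int = 0
    max_features: int | str = "sqrt"
    bootstrap: bool = True
    rng_seed: int = 0
    min_samples_split: int = 2
    max_depth: int | None = None
    n_jobs: int = 1

    def resolve_max_features(self, n_features: int) -> int:
        if self.max_features == "sqrt":
            m = int(np.ceil(np.sqrt(n_features)))
        else:
            m = int(self.max_features)
        if not 1 <= m <= n_features:
            raise ValueError(
                f"max_features={self.max_features!r} must resolve to 1..{n_features}"
            )
        return m

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass(frozen=True)
class LatentSplitRecord:
    """Frozen record of one latent split, sufficient to project new samples.

    The latent score of a sample x is
    ``sum_m projection[m] * (x[members[m]] - center[m]) / scale[m]``;
    the sample goes left iff the score is <= ``threshold``.  ``loadings`` is
    sigma1 * v1 — the covariance between the latent variable and each scaled
    member — and is what distributes the split's Gini gain over the
    neighbourhood.  The sign is fixed so the largest-|loading| entry is
    positive (predictions are sign-invariant; serialization is not).
    """

    foi: int
    members: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    projection: np.ndarray
    loadings: np.ndarray
    threshold: float
    gain: float
    constant_members: np.ndarray  # bool flags: member column constant at node

    def project(self, X: np.ndarray) -> np.ndarray:
        """Latent scores for samples in X (2D: n x n_features)."""
        Z = (X[:, self.members] - self.center) / self.scale
        return Z @ self.projection


@dataclass
class TreeNode:
    """Internal node (split + two children) or leaf (label + class counts)."""

    split: LatentSplitRecord | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: object = None
    counts: np.ndarray | None = None  # per-class training counts at a leaf

    @property
    def is_leaf(self) -> bool:
        return self.split is None


def gini_index(labels: np.ndarray) -> float:
    """Gini impurity: one minus the sum of squared class probabilities."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini_index of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.dot(p, p))


def gini_gain(parent: np.ndarray, left: np.ndarray, right: np.ndarray) -> float:
    """Impurity decrease: G(parent) - weighted child impurities."""
    parent, left, right = (np.asarray(a) for a in (parent, left, right))
    if left.size == 0 or right.size == 0:
        raise ValueError("both children must be non-empty")
    if left.size + right.size != parent.size:
        raise ValueError("children must partition the parent")
    n = parent.size
    return (
        gini_index(parent)
        - (left.size / n) * gini_index(left)
        - (right.size / n) * gini_index(right)
    )


@dataclass(frozen=True)
class _LatentBasis:
    """Partial split record: scaling + projection, before threshold search."""

    center: np.ndarray
    scale: np.ndarray
    projection: np.ndarray
    loadings: np.ndarray
    constant_members: np.ndarray


def compute_latent(submatrix: np.ndarray) -> tuple[np.ndarray, _LatentBasis] | None:
    """Latent scores of a node's neighbourhood sub-matrix via SVD.

    Columns are autoscaled (mean 0, population variance 1) over the node's
    samples; constant columns get scale 1 and are flagged.  The SVD of the
    scaled matrix Z = U S V^T yields scores = Z @ v1 (proportional to the
    first left singular vector u1) and loadings = s1 * v1.  Returns ``None``
    when every column is constant — the candidate carries no information.
    """
    Z = np.asarray(submatrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("submatrix must be 2D with at least 2 rows")
    center = Z.mean(axis=0)
    sd = Z.std(axis=0)
    constant = sd <= _SCALE_EPS
    if constant.all():
        return None
    scale = np.where(constant, 1.0, sd)
    Z = (Z - center) / scale
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    v1 = Vt[0]
    loadings = s[0] * v1
    # sign convention: largest-|loading| member positive
    j = int(np.argmax(np.abs(loadings)))
    if loadings[j] < 0:
        v1 = -v1
        loadings = -loadings
    scores = Z @ v1
    return scores, _LatentBasis(center, scale, v1, loadings, constant)


def best_split(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float] | None:
    """Best Gini split over latent scores.

    Evaluates thresholds at midpoints between consecutive distinct sorted
    scores, with ``score <= threshold`` going left.  Returns the
    (threshold, gain) with maximal gain, ties broken toward the lower
    threshold; ``None`` when all scores are equal or no split has positive
    gain.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must be aligned")
    n = scores.shape[0]
    if n < 2:
        return None
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    classes, y = np.unique(labels, return_inverse=True)
    y = y[order]
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), y] = 1.0
    cum = np.cumsum(onehot, axis=0)  # cum[i] = class counts among first i+1
    total = cum[-1]
    cut = np.flatnonzero(s[:-1] < s[1:])  # left block = first cut+1 samples
    if cut.size == 0:
        return None
    n_left = (cut + 1).astype(float)
    n_right = n - n_left
    left_counts = cum[cut]
    right_counts = total - left_counts
    g_parent = 1.0 - np.sum((total / n) ** 2)
    g_left = 1.0 - np.sum((left_counts / n_left[:, None]) ** 2, axis=1)
    g_right = 1.0 - np.sum((right_counts / n_right[:, None]) ** 2, axis=1)
    gains = g_parent - (n_left / n) * g_left - (n_right / n) * g_right
    # lowest threshold among gains tied within tolerance
    best = int(np.flatnonzero(gains >= gains.max() - GAIN_TIE_TOL)[0])
    if gains[best] <= GAIN_TIE_TOL:
        return None
    i = cut[best]
    threshold = 0.5 * (s[i] + s[i + 1])
    # guard against midpoint collapsing onto a neighbour under float rounding
    if not (s[i] <= threshold < s[i + 1]):
        threshold = s[i]
    return float(threshold), float(gains[best])


def _majority_leaf(y_codes: np.ndarray, n_classes: int) -> TreeNode:
    counts = np.bincount(y_codes, minlength=n_classes)
    return TreeNode(label=int(np.argmax(counts)), counts=counts)


def grow_tree(
    X: np.ndarray,
    y_codes: np.ndarray,
    nmap,
    cfg: FitConfig,
    rng: np.random.Generator,
    n_classes: int,
    ledger: TreeLedger | None = None,
) -> tuple[TreeNode, TreeLedger]:
    """Grow one latent tree on (X, y_codes) and record ledger events.

    ``y_codes`` are integer class codes (0..n_classes-1).  At every node
    ``max_features`` candidate FOIs are drawn without replacement from all
    features; each candidate is recorded as *evaluated*, the winner (maximal
    gain, ties toward the lower FOI index) as *selected*, with its gain
    distributed over the neighbourhood by absolute loadings.  Recursion stops
    at purity, ``min_samples_split`` or ``max_depth``, yielding a
    majority-label leaf.
    """
    X = np.asarray(X, dtype=float)
    y_codes = np.asarray(y_codes, dtype=np.intp)
    n_samples, n_features = X.shape
    if len(nmap) != n_features:
        raise ValueError("neighbourhood map does not match n_features")
    mf = cfg.resolve_max_features(n_features)
    if ledger is None:
        ledger = TreeLedger(n_features)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y_node = y_codes[idx]
        if (
            y_node.size < cfg.min_samples_split
            or (y_node == y_node[0]).all()
            or (cfg.max_depth is not None and depth >= cfg.max_depth)
        ):
            return _majority_leaf(y_node, n_classes)
        candidates = rng.choice(n_features, size=mf, replace=False)
        ledger.record_evaluated(candidates)
        best_record = None
        best_scores = None
        # ascending order + strict improvement = lower-FOI tie-break
        for foi in np.sort(candidates):
            latent = compute_latent(X[np.ix_(idx, nmap[foi])])
            if latent is None:
                continue
            scores, basis = latent
            found = best_split(scores, y_node)
            if found is None:
                continue
            threshold, gain = found
            if best_record is None or gain > best_record.gain + GAIN_TIE_TOL:
                best_record = LatentSplitRecord(
                    foi=int(foi),
                    members=np.asarray(nmap[foi], dtype=np.intp),
                    center=basis.center,
                    scale=basis.scale,
                    projection=basis.projection,
                    loadings=basis.loadings,
                    threshold=threshold,
                    gain=gain,
                    constant_members=basis.constant_members,
                )
                best_scores = scores
        if best_record is None:
            return _majority_leaf(y_node, n_classes)
        go_left = best_scores <= best_record.threshold
        if not go_left.any() or go_left.all():  # degenerate float partition
            return _majority_leaf(y_node, n_classes)
        ledger.record_selected(best_record)
        node = TreeNode(split=best_record)
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(n_samples), 0)
    return root, ledger


def predict_tree(node: TreeNode, x: np.ndarray) -> int:
    """Route one sample down the tree; returns the leaf's class code."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    while not node.is_leaf:
        score = node.split.project(x[None, :])[0]
        node = node.left if score <= node.split.threshold else node.right
    return node.label


def predict_tree_matrix(root: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vectorized traversal: class codes for every row of X."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=np.intp)

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.label
            return
        scores = node.split.project(X[idx])
        left = scores <= node.split.threshold
        route(node.left, idx[left])
        route(node.right, idx[~left])

    route(root, np.arange(X.shape[0]))
    return out
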