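"""Bootstrap ensemble of latent trees with majority-vote prediction.

Per-tree randomness is drawn from independent child streams spawned from the
forest seed, so the forest is bit-identical for a given seed regardless of
how many workers build the trees, and adding trees never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .importance import ImportanceReport, TreeLedger, final_importance
from .latent_tree import FitConfig, TreeNode, grow_tree, predict_tree_matrix
from .neighborhoods import NeighborhoodMap

__all__ = ["LavasetForest", "fit_forest", "predict", "predict_proba"]


@dataclass
class LavasetForest:
    """A fitted forest: trees, merged ledger, and training class ordering.

    ``class_labels`` preserves the order of first appearance in the training
    labels; prediction ties are broken toward the earlier class.
    """

    trees: list[TreeNode]
    cfg: FitConfig
    nmap: NeighborhoodMap
    ledger: TreeLedger
    class_labels: np.ndarray
    tree_seeds: list[int] = field(default_factory=list)
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def importance_report(self) -> ImportanceReport:
        return final_importance(self.ledger)


def _grow_one(X, y_codes, nmap, cfg, seed_state, n_classes):
    rng = np.random.Generator(np.random.PCG64(seed_state))
    n = X.shape[0]
    if cfg.bootstrap:
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y_codes[idx]
    else:
        Xb, yb = X, y_codes
    return grow_tree(Xb, yb, nmap, cfg, rng, n_classes)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    nmap: NeighborhoodMap,
    cfg: FitConfig,
) -> LavasetForest:
    """Fit ``cfg.n_trees`` latent trees and merge their ledgers.

    Bootstrap samples (n draws with replacement) are taken per tree when
    ``cfg.bootstrap``.  Trees may be grown in parallel (``cfg.n_jobs``); the
    merged ledger and forest are identical to sequential execution because
    per-tree seeds are pre-spawned and ledgers are merged in tree order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    class_labels = _unique_ordered(y)
    if class_labels.shape[0] < 2:
        raise ValueError("need at least two classes to fit")
    code_of = {c: i for i, c in enumerate(class_labels.tolist())}
    y_codes = np.asarray([code_of[v] for v in y.tolist()], dtype=np.intp)
    if len(nmap) != X.shape[1]:
        raise ValueError(
            f"neighbourhood map covers {len(nmap)} features but X has {X.shape[1]}"
        )
    cfg.resolve_max_features(X.shape[1])  # fail fast on bad max_features

    ss = np.random.SeedSequence(cfg.rng_seed)
    children = ss.spawn(cfg.n_trees)
    results = Parallel(n_jobs=cfg.n_jobs, prefer="processes")(
        delayed(_grow_one)(X, y_codes, nmap, cfg, child, class_labels.shape[0])
        for child in children
    ) if cfg.n_jobs != 1 else [
        _grow_one(X, y_codes, nmap, cfg, child, class_labels.shape[0])
        for child in children
    ]

    ledger = TreeLedger(X.shape[1])
    trees = []
    for root, tree_ledger in results:  # merge in tree order: order-stable sums
        trees.append(root)
        ledger.merge(tree_ledger)
    tree_seeds = [int(c.generate_state(1)[0]) for c in children]
    return LavasetForest(
        trees=trees,
        cfg=cfg,
        nmap=nmap,
        ledger=ledger,
        class_labels=class_labels,
        tree_seeds=tree_seeds,
        n_features=X.shape[1],
    )


def _unique_ordered(y: np.ndarray) -> np.ndarray:
    """Unique labels in order of first appearance."""
    _, first = np.unique(y, return_index=True)
    return y[np.sort(first)]


def _votes(forest: LavasetForest, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"X must have {forest.n_features} columns, got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n_classes = forest.class_labels.shape[0]
    votes = np.zeros((X.shape[0], n_classes), dtype=np.int64)
    rows = np.arange(X.shape[0])
    for root in forest.trees:
        votes[rows, predict_tree_matrix(root, X)] += 1
    return votes


def predict(forest: LavasetForest, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels; ties go to the earlier class in class_labels."""
    votes = _votes(forest, X)
    return forest.class_labels[np.argmax(votes, axis=1)]


def predict_proba(forest: LavasetForest, X: np.ndarray) -> np.ndarray:
    """Per-class vote fractions, columns ordered as class_labels."""
    votes = _votes(forest, X)
    return votes / votes.sum(axis=1, keepdims=True)
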