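"""Model evaluation: classification metrics, peak coverage, grid search.

Peak coverage scores an importance vector against the known discriminative
points: the positives are the ground-truth peak points; for each contiguous
peak, k off-peak flanking points (ceil(k/2) immediately left, floor(k/2)
immediately right) are designated true negatives — the flanks are exactly
where neighbourhood spill could cause false positives.  A point is called
positive iff its importance is > 0, so the measure is invariant to any
monotone rescaling of the importance vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .ensemble import fit_forest, predict
from .latent_tree import FitConfig
from .neighborhoods import from_distance_matrix, from_spectral_axis
from .synthetic_data import GroundTruth

__all__ = [
    "CoverageResult",
    "classification_metrics",
    "peak_coverage",
    "grid_search",
]


@dataclass(frozen=True)
class CoverageResult:
    """Peak-coverage precision/recall/F1 with the underlying point counts."""

    precision: float
    recall: float
    f1: float
    n_true_positive_points: int
    n_false_negative_points: int
    n_false_positive_points: int
    precision_defined: bool = True


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    positive_label=None,
) -> dict:
    """Accuracy, precision, recall, F1 for a label pair.

    Binary problems score the declared ``positive_label`` (default: the
    larger label under sorting); more than two classes fall back to
    macro-averaging.  Undefined precision (no positive predictions) is
    reported as 0 with ``precision_defined=False``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    acc = accuracy_score(y_true, y_pred)
    if labels.size <= 2:
        if positive_label is None:
            positive_label = labels[-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, pos_label=positive_label, average="binary",
                zero_division=0,
            )
        defined = bool(np.any(y_pred == positive_label))
    else:
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
        defined = True
    return {
        "accuracy": float(acc),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
        "precision_defined": defined,
    }


def _peak_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of True in mask."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def peak_coverage(importance: np.ndarray, truth: GroundTruth, k: int) -> CoverageResult:
    """Score an importance vector against the ground-truth peak points."""
    importance = np.asarray(importance, dtype=float)
    mask = np.asarray(truth.mask, dtype=bool)
    if importance.shape[0] != mask.shape[0]:
        raise ValueError("importance length must equal n_features")
    if k < 0:
        raise ValueError("k must be non-negative")
    n = mask.shape[0]
    left_n = int(np.ceil(k / 2))
    right_n = k - left_n  # floor(k/2)
    flanks: set[int] = set()
    overlapped = False
    for start, stop in _peak_runs(mask):
        left = range(max(start - left_n, 0), start)
        right = range(stop, min(stop + right_n, n))
        for i in list(left) + list(right):
            if mask[i]:
                overlapped = True
                continue
            if i in flanks:
                overlapped = True
            flanks.add(i)
    if overlapped:
        warnings.warn("flank regions of adjacent peaks overlap; merged", stacklevel=2)
    called = importance > 0
    tp = int(np.sum(called & mask))
    fn = int(np.sum(~called & mask))
    flank_idx = np.fromiter(flanks, dtype=np.intp) if flanks else np.empty(0, dtype=np.intp)
    fp = int(np.sum(called[flank_idx])) if flank_idx.size else 0
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return CoverageResult(
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        n_true_positive_points=tp,
        n_false_negative_points=fn,
        n_false_positive_points=fp,
        precision_defined=defined,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    axis_or_distance: np.ndarray,
    tree_grid,
    neighbor_grid,
    n_repeats: int = 1,
    seed: int = 0,
    test_size: float = 0.2,
    stratify: bool = True,
) -> pd.DataFrame:
    """Held-out metrics over a trees x neighbours grid.

    A single stratified (by default) 80/20 split is fixed up front and shared
    by every combination; each combination is refit ``n_repeats`` times with
    repeat seeds that are identical across combinations, so compared models
    see the same bootstrap randomness.  Returns one row per (n_trees, k) with
    mean and sd of the held-out metrics; combinations that fail to fit are
    recorded with NaN metrics and the run continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    tree_grid = list(tree_grid)
    neighbor_grid = list(neighbor_grid)
    if not tree_grid or not neighbor_grid:
        raise ValueError("grids must be non-empty")
    axis_or_distance = np.asarray(axis_or_distance, dtype=float)

    idx = np.arange(X.shape[0])
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_size,
        random_state=seed,
        stratify=y if stratify else None,
    )
    repeat_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)

    rows = []
    metric_names = ("accuracy", "precision", "recall", "f1")
    for k in neighbor_grid:
        nmap = (
            from_spectral_axis(axis_or_distance, k)
            if axis_or_distance.ndim == 1
            else from_distance_matrix(axis_or_distance, k)
        )
        for n_trees in tree_grid:
            per_repeat = {m: [] for m in metric_names}
            failed = False
            for r_seed in repeat_seeds:
                try:
                    cfg = FitConfig(n_trees=int(n_trees), k_neighbors=int(k),
                                    rng_seed=int(r_seed))
                    forest = fit_forest(X[train_idx], y[train_idx], nmap, cfg)
                    m = classification_metrics(y[test_idx], predict(forest, X[test_idx]))
                except Exception as exc:  # noqa: BLE001 — record and continue
                    warnings.warn(
                        f"fit failed for n_trees={n_trees}, k={k}: {exc}", stacklevel=2
                    )
                    failed = True
                    break
                for name in metric_names:
                    per_repeat[name].append(m[name])
            row = {"n_trees": int(n_trees), "k": int(k), "n_repeats": n_repeats}
            for name in metric_names:
                vals = np.asarray(per_repeat[name])
                row[f"{name}_mean"] = float(vals.mean()) if not failed else np.nan
                row[f"{name}_sd"] = float(vals.std()) if not failed else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
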