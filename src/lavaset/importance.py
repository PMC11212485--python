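"""Feature-importance bookkeeping and the final importance score.

During fitting, three per-feature accumulators are kept across all trees:

* ``evaluated`` — how many node visits had the feature among the candidate
  FOIs (every candidate counts once per node);
* ``selected`` — how many splits the feature won as the FOI;
* ``gini`` — the feature's accumulated share of split Gini gains.

A winning split's gain is not credited to the FOI alone: it is distributed
over every member of the winning neighbourhood with weights proportional to
the absolute loadings, so the distribution conserves the gain exactly and
correlated neighbours of an informative feature accrue importance too.

The final score of feature i is the product of its normalized accumulated
gain and its selection frequency:

    importance(i) = gini(i) / sum_f gini(f)  *  selected(i) / evaluated(i)

Features never evaluated get importance 0.  The report also carries the raw
accumulators and the gain-per-selection ratio as auxiliary columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TreeLedger",
    "ImportanceReport",
    "record_evaluated",
    "record_selected",
    "final_importance",
]


class TreeLedger:
    """Per-feature evaluated/selected/gini accumulators.

    Used both per tree (then merged by summation) and for the whole forest.
    """

    __slots__ = ("evaluated", "selected", "gini")

    def __init__(self, n_features: int):
        self.evaluated = np.zeros(n_features, dtype=np.int64)
        self.selected = np.zeros(n_features, dtype=np.int64)
        self.gini = np.zeros(n_features, dtype=np.float64)

    @property
    def n_features(self) -> int:
        return self.evaluated.shape[0]

    def record_evaluated(self, candidate_fois: np.ndarray) -> "TreeLedger":
        """Count one node visit for each candidate FOI."""
        self.evaluated[np.asarray(candidate_fois, dtype=np.intp)] += 1
        return self

    def record_selected(self, split) -> "TreeLedger":
        """Credit a winning split: FOI selection + loading-weighted gain.

        ``split`` needs fields foi, members, loadings, gain (a
        LatentSplitRecord).  Weights are |loadings| normalized to sum 1, so
        the total credited equals ``split.gain`` exactly.
        """
        if split.gain < 0:
            raise ValueError("split gain must be non-negative")
        w = np.abs(np.asarray(split.loadings, dtype=float))
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero loadings cannot distribute gain")
        self.selected[split.foi] += 1
        self.gini[np.asarray(split.members, dtype=np.intp)] += split.gain * (w / total)
        return self

    def merge(self, other: "TreeLedger") -> "TreeLedger":
        self.evaluated += other.evaluated
        self.selected += other.selected
        self.gini += other.gini
        return self

    def copy(self) -> "TreeLedger":
        out = TreeLedger(self.n_features)
        out.evaluated[:] = self.evaluated
        out.selected[:] = self.selected
        out.gini[:] = self.gini
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TreeLedger)
            and np.array_equal(self.evaluated, other.evaluated)
            and np.array_equal(self.selected, other.selected)
            and np.array_equal(self.gini, other.gini)
        )


def record_evaluated(ledger: TreeLedger, candidate_fois) -> TreeLedger:
    """Functional alias of :meth:`TreeLedger.record_evaluated`."""
    return ledger.record_evaluated(candidate_fois)


def record_selected(ledger: TreeLedger, split) -> TreeLedger:
    """Functional alias of :meth:`TreeLedger.record_selected`."""
    return ledger.record_selected(split)


@dataclass(frozen=True)
class ImportanceReport:
    """Final per-feature importances plus the two factors they combine."""

    importance: np.ndarray
    normalized_gini: np.ndarray
    selection_ratio: np.ndarray
    evaluated: np.ndarray
    selected: np.ndarray
    gini: np.ndarray

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        n = self.importance.shape[0]
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(n)]
        with np.errstate(invalid="ignore", divide="ignore"):
            gain_per_sel = np.where(self.selected > 0, self.gini / np.maximum(self.selected, 1), 0.0)
        return pd.DataFrame(
            {
                "feature_id": list(feature_ids),
                "evaluated": self.evaluated,
                "selected": self.selected,
                "gini": self.gini,
                "normalized_gini": self.normalized_gini,
                "selection_ratio": self.selection_ratio,
                "importance": self.importance,
                "gini_per_selection": gain_per_sel,
            }
        )


def final_importance(ledger: TreeLedger) -> ImportanceReport:
    """Combine the ledger into final importances.

    Emits an all-zero report with a warning when no split occurred anywhere.
    """
    total_gini = ledger.gini.sum()
    n = ledger.n_features
    if total_gini <= 0:
        warnings.warn("no splits were recorded; importances are all zero", stacklevel=2)
        zero = np.zeros(n)
        return ImportanceReport(zero, zero.copy(), zero.copy(),
                                ledger.evaluated.copy(), ledger.selected.copy(),
                                ledger.gini.copy())
    normalized_gini = ledger.gini / total_gini
    selection_ratio = np.where(
        ledger.evaluated > 0,
        ledger.selected / np.maximum(ledger.evaluated, 1),
        0.0,
    )
    importance = normalized_gini * selection_ratio
    return ImportanceReport(
        importance=importance,
        normalized_gini=normalized_gini,
        selection_ratio=selection_ratio,
        evaluated=ledger.evaluated.copy(),
        selected=ledger.selected.copy(),
        gini=ledger.gini.copy(),
    )
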