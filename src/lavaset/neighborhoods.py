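"""Per-feature neighbourhood construction.

Every latent split operates on a *feature-of-interest* (FOI) together with its
k nearest features under a user-chosen distance structure.  This module builds
the :class:`NeighborhoodMap` — for each feature, an ordered list of member
indices with the FOI first — from any of four sources:

* a precomputed feature x feature distance matrix,
* a 1D spectral axis (e.g. an NMR ppm scale),
* a cyclic multi-channel time grid (e.g. the three VCG leads over a cardiac
  cycle, where the first and last time points are adjacent),
* per-sample 3D coordinates with a consensus vote across samples (e.g. points
  on anatomical meshes that deform sample to sample).

Conventions shared by all modes: ``k`` counts neighbours *excluding* the FOI
itself (so ``k=0`` reduces the ensemble to a classic random forest), and ties
at equal distance are broken toward the lower feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborhoodMap",
    "from_distance_matrix",
    "from_spectral_axis",
    "from_cyclic_multichannel",
    "from_spatial_consensus",
    "validate_distance_matrix",
]


@dataclass(frozen=True)
class NeighborhoodMap:
    """Ordered member lists for every feature's neighbourhood.

    Attributes
    ----------
    members
        ``members[f]`` is an int array whose first entry is ``f`` itself,
        followed by its neighbours.  All modes yield ``k + 1`` members except
        spatial consensus, where features may retain fewer survivors.
    k
        Nominal neighbour count, excluding the FOI.
    source
        Construction tag: ``precomputed``, ``spectral``,
        ``cyclic_multichannel`` or ``spatial_consensus``.
    """

    members: tuple[np.ndarray, ...]
    k: int
    source: str
    n_features: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_features", len(self.members))

    def __len__(self) -> int:
        return self.n_features

    def __getitem__(self, f: int) -> np.ndarray:
        return self.members[f]

    def validate(self) -> None:
        """Check self-membership, bounds and uniqueness of every list."""
        n = self.n_features
        for f, mem in enumerate(self.members):
            if mem.size == 0 or mem[0] != f:
                raise ValueError(f"neighbourhood of feature {f} must list {f} first")
            if len(np.unique(mem)) != mem.size:
                raise ValueError(f"duplicate members in neighbourhood of feature {f}")
            if mem.min() < 0 or mem.max() >= n:
                raise ValueError(f"member index out of range for feature {f}")


def validate_distance_matrix(D: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate a feature distance matrix: square, symmetric, zero diagonal."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    asym = np.abs(D - D.T)
    if asym.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"distance matrix is asymmetric: D[{i},{j}]={D[i, j]!r} vs D[{j},{i}]={D[j, i]!r}"
        )
    if np.abs(np.diag(D)).max(initial=0.0) > tol:
        i = int(np.argmax(np.abs(np.diag(D))))
        raise ValueError(f"distance matrix diagonal must be zero; D[{i},{i}]={D[i, i]!r}")
    return D


def _check_k(k: int, n_features: int) -> int:
    k = int(k)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= n_features:
        raise ValueError(f"k={k} must be smaller than n_features={n_features}")
    return k


def from_distance_matrix(D: np.ndarray, k: int) -> NeighborhoodMap:
    """Neighbourhoods from a precomputed feature x feature distance matrix.

    ``members[f]`` is ``f`` followed by the ``k`` features with smallest
    ``D[f, :]`` (self excluded); ties broken by lower index.
    """
    D = validate_distance_matrix(D)
    n = D.shape[0]
    k = _check_k(k, n)
    members = []
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    for f in range(n):
        # stable sort keeps lower indices first among equal distances
        order = np.argsort(work[f], kind="stable")[:k]
        members.append(np.concatenate(([f], order)).astype(np.intp))
    return NeighborhoodMap(tuple(members), k=k, source="precomputed")


def from_spectral_axis(axis: np.ndarray, k: int) -> NeighborhoodMap:
    """Neighbourhoods from a strictly monotone 1D axis (e.g. ppm scale).

    Equivalent to :func:`from_distance_matrix` on ``|axis[i] - axis[j]|``
    without materializing the full matrix: neighbours are gathered with a
    two-pointer sweep outward from each feature.
    """
    axis = np.asarray(axis, dtype=float).ravel()
    n = axis.size
    diffs = np.diff(axis)
    if n > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("axis must be strictly monotone")
    k = _check_k(k, n)
    members = []
    for f in range(n):
        mem = np.empty(k + 1, dtype=np.intp)
        mem[0] = f
        lo, hi = f - 1, f + 1
        for m in range(1, k + 1):
            if lo < 0:
                pick = hi
                hi += 1
            elif hi >= n:
                pick = lo
                lo -= 1
            else:
                dl = abs(axis[f] - axis[lo])
                dr = abs(axis[hi] - axis[f])
                # tie -> lower feature index, which is always the left pointer
                if dl <= dr:
                    pick = lo
                    lo -= 1
                else:
                    pick = hi
                    hi += 1
            mem[m] = pick
        members.append(mem)
    return NeighborhoodMap(tuple(members), k=k, source="spectral")


def from_cyclic_multichannel(n_channels: int, n_timepoints: int, steps: int) -> NeighborhoodMap:
    """Neighbourhoods on a cyclic multi-channel time grid.

    Features are indexed channel-major: feature ``c * n_timepoints + t`` is
    channel ``c`` at time ``t``.  The neighbourhood of (c, i) contains every
    channel at times ``i, i±1, …, i±steps`` with cyclic wrap (the first and
    last time points of the cycle are adjacent), so each neighbourhood has
    ``n_channels * (2*steps + 1)`` members.  With three channels, each extra
    step adds six members — the three leads at both i+d and i-d.
    """
    n_channels, n_timepoints, steps = int(n_channels), int(n_timepoints), int(steps)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if 2 * steps + 1 > n_timepoints:
        raise ValueError(
            f"window of 2*steps+1={2 * steps + 1} time points exceeds the "
            f"cycle length {n_timepoints}: windows would self-overlap"
        )
    size = n_channels * (2 * steps + 1)
    members = []
    for c in range(n_channels):
        for t in range(n_timepoints):
            foi = c * n_timepoints + t
            mem = [foi]
            for d in range(steps + 1):
                times = (t,) if d == 0 else ((t - d) % n_timepoints, (t + d) % n_timepoints)
                for tt in times:
                    for cc in range(n_channels):
                        idx = cc * n_timepoints + tt
                        if idx != foi:
                            mem.append(idx)
            members.append(np.asarray(mem, dtype=np.intp))
            assert members[-1].size == size
    return NeighborhoodMap(tuple(members), k=size - 1, source="cyclic_multichannel")


def from_spatial_consensus(
    coords: np.ndarray,
    k: int,
    consensus_fraction: float = 0.5,
) -> NeighborhoodMap:
    """Consensus neighbourhoods from per-sample 3D coordinates.

    For each feature (point), the k nearest points are found per sample by
    Euclidean distance; only points that are neighbours in strictly more than
    ``consensus_fraction`` of samples are retained.  Survivors are ordered by
    descending appearance frequency, ties by mean within-sample rank, then by
    index, and truncated to the k best-supported.  A feature may end up with
    fewer than k survivors — they are kept as-is (no padding), with a
    warning.

    Parameters
    ----------
    coords
        Array of shape (n_samples, n_points, 3) — one coordinate block per
        sample, all sharing the same point count.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError(
            f"coords must have shape (n_samples, n_points, 3), got {coords.shape}"
        )
    n_samples, n_points, _ = coords.shape
    if not 0.0 < consensus_fraction < 1.0:
        raise ValueError("consensus_fraction must be in (0, 1)")
    k = _check_k(k, n_points)

    # per-sample kNN: counts[f, j] = number of samples where j is in f's kNN,
    # rank_sum[f, j] = summed rank positions (1-based) over those samples
    counts = np.zeros((n_points, n_points), dtype=np.int64)
    rank_sum = np.zeros((n_points, n_points), dtype=np.float64)
    rows = np.repeat(np.arange(n_points), k)
    for s in range(n_samples):
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords[s])
        _, idx = nn.kneighbors(coords[s])
        # drop self from each row (distance 0; may not be first among ties)
        neigh = np.stack([row[row != f][:k] for f, row in enumerate(idx)], axis=0)
        cols = neigh.ravel()
        counts[rows, cols] += 1
        rank_sum[rows, cols] += np.tile(np.arange(1, k + 1), n_points)

    threshold = consensus_fraction * n_samples
    members = []
    short = 0
    for f in range(n_points):
        cand = np.flatnonzero(counts[f] > threshold)
        cand = cand[cand != f]
        if cand.size:
            freq = counts[f, cand]
            mean_rank = rank_sum[f, cand] / freq
            order = np.lexsort((cand, mean_rank, -freq))
            cand = cand[order][:k]  # at most k survivors, best-supported first
        if cand.size < k:
            short += 1
        members.append(np.concatenate(([f], cand)).astype(np.intp))
    if short:
        warnings.warn(
            f"{short} of {n_points} features retained fewer than k={k} "
            f"consensus neighbours (threshold {consensus_fraction:g} of "
            f"{n_samples} samples)",
            stacklevel=2,
        )
    return NeighborhoodMap(tuple(members), k=k, source="spatial_consensus")
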