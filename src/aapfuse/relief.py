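"""Relief feature weighting and incremental feature selection (IFS).

Relief scores each feature by how well it separates nearest neighbours of
opposite classes.  For each visited sample ``s``, the nearest same-class
neighbour NH(s) ("nearest hit") and nearest other-class neighbour NM(s)
("nearest miss") are found by Euclidean distance, and every feature weight
is updated

    W_p  <-  W_p - |s_p - NH(s)_p| / n + |s_p - NM(s)_p| / n

so features that differ across the class boundary but not within a class
accumulate positive weight.  Features are min–max scaled to [0, 1] before
any distance or diff, which makes the weights invariant to affine
rescaling of individual features.  By default every sample is visited once
in index order (``n_iter="all"``), making the result deterministic;
``n_iter=<int>`` samples instances with replacement from a seeded RNG.

IFS then walks the Relief ranking: for k = 1..d it evaluates a supplied
scorer (typically cross-validated accuracy of the fused classifier) on the
top-k features and keeps the smallest k attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass
class ReliefResult:
    weights: np.ndarray      #: one weight per feature
    ranking: np.ndarray      #: feature indices, best first, ties by index
    n_iter: int              #: number of instance visits performed
    seed: int


@dataclass
class IFSResult:
    curve: np.ndarray        #: accuracy at each prefix size k = 1..d
    chosen_k: int            #: smallest k attaining max(curve)
    selected: np.ndarray     #: ranking[:chosen_k]


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    scaled = np.zeros_like(X, dtype=float)
    nz = span > 0
    scaled[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return scaled


def relief_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int | str = "all",
    seed: int = 0,
) -> ReliefResult:
    """Rank features by Relief weights on a binary-labelled matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("Relief requires exactly two classes")
    if counts.min() < 2:
        raise ValueError(
            "each class needs >= 2 samples (nearest hit undefined otherwise)"
        )

    n, d = X.shape
    Xs = _minmax_scale(X)
    if n_iter == "all":
        visits = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        visits = rng.integers(0, n, size=int(n_iter))

    weights = np.zeros(d)
    m = len(visits)
    for i in visits:
        diffs = np.abs(Xs - Xs[i])           # (n, d)
        dist = np.sqrt((diffs ** 2).sum(axis=1))
        same = y == y[i]
        dist_hit = np.where(same, dist, np.inf)
        dist_hit[i] = np.inf                  # self excluded
        dist_miss = np.where(~same, dist, np.inf)
        nh = int(np.argmin(dist_hit))         # argmin ties -> lowest index
        nm = int(np.argmin(dist_miss))
        weights += (diffs[nm] - diffs[nh]) / m

    # descending weight, ties broken by ascending original index
    ranking = np.lexsort((np.arange(d), -weights))
    return ReliefResult(weights=weights, ranking=ranking, n_iter=m, seed=seed)


def ifs_select(
    X: np.ndarray,
    y: np.ndarray,
    ranking: Sequence[int],
    evaluator: Callable[[np.ndarray, np.ndarray], float],
) -> IFSResult:
    """Pick the best prefix of a feature ranking by forward evaluation.

    ``evaluator(X_subset, y)`` must return an accuracy in [0, 1]; it is
    called exactly once per prefix length ``k = 1..d``.
    """
    X = np.asarray(X, dtype=float)
    ranking = np.asarray(ranking, dtype=int)
    if sorted(ranking.tolist()) != list(range(X.shape[1])):
        raise ValueError("ranking must be a permutation of all feature indices")
    d = len(ranking)
    curve = np.empty(d)
    for k in range(1, d + 1):
        acc = float(evaluator(X[:, ranking[:k]], y))
        if not (0.0 <= acc <= 1.0):
            raise ValueError(f"evaluator returned {acc} outside [0, 1] at k={k}")
        curve[k - 1] = acc
    chosen_k = int(np.argmax(curve)) + 1      # argmax -> smallest k on ties
    return IFSResult(curve=curve, chosen_k=chosen_k, selected=ranking[:chosen_k])
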