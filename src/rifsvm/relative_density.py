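"""K-th nearest-neighbor distances within and across classes (KNN-PDE).

The reciprocal of an instance's k-th NN distance is its *relative density*:
a large k-th NN distance means a sparse neighborhood, i.e., low density, the
hallmark of noise and outliers. Only the distances themselves are needed —
ratios of relative densities reduce to inverse ratios of k-th NN distances,
so no explicit density estimate is ever formed.

k follows the square-root policy k = ceil(multiplier * sqrt(N_class)), one k
per class, clamped so the k-th neighbor exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["KPolicy", "DensityProfile", "k_from_multiplier", "kth_nn_distance", "density_profile"]


def k_from_multiplier(N: int, multiplier: float = 1.0) -> int:
    """ceil(multiplier * sqrt(N)) clamped to [1, N-1]."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    return int(min(max(math.ceil(multiplier * math.sqrt(N)), 1), N - 1))


@dataclass(frozen=True)
class KPolicy:
    """Neighbor-count policy: sqrt rule (scaled by ``multiplier``) or explicit ks."""

    mode: str = "sqrt"
    multiplier: float = 1.0
    k_pos: int | None = None
    k_neg: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("sqrt", "explicit"):
            raise ValueError("mode must be 'sqrt' or 'explicit'")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if self.mode == "explicit" and (self.k_pos is None or self.k_neg is None):
            raise ValueError("explicit mode requires k_pos and k_neg")

    def resolve(self, n_pos: int, n_neg: int) -> tuple[int, int]:
        """Return (k+, k-) for class sizes (N+, N-)."""
        if self.mode == "explicit":
            k_pos, k_neg = int(self.k_pos), int(self.k_neg)
            if k_pos < 1 or k_neg < 1:
                raise ValueError("explicit k values must be >= 1")
            return min(k_pos, n_pos - 1), min(k_neg, n_neg - 1)
        return k_from_multiplier(n_pos, self.multiplier), k_from_multiplier(n_neg, self.multiplier)


@dataclass(frozen=True)
class DensityProfile:
    """Per-instance within/between-class k-th NN distances and class maxima.

    ``d_within[i]`` uses instance i's own class (self excluded, k = own class's
    k); ``d_between[i]`` uses the opposite class (k = opposite class's k).
    The four normalizers are the maxima of those distances taken over the
    instances of each class.
    """

    labels: np.ndarray
    d_within: np.ndarray
    d_between: np.ndarray
    k_pos: int
    k_neg: int

    def _max_over(self, values: np.ndarray, label: int) -> float:
        return float(values[self.labels == label].max())

    @property
    def max_within_pos(self) -> float:
        return self._max_over(self.d_within, 1)

    @property
    def max_within_neg(self) -> float:
        return self._max_over(self.d_within, -1)

    @property
    def max_between_pos(self) -> float:
        return self._max_over(self.d_between, 1)

    @property
    def max_between_neg(self) -> float:
        return self._max_over(self.d_between, -1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"label": self.labels, "d_within": self.d_within, "d_between": self.d_between}
        )


def kth_nn_distance(query: np.ndarray, reference_set: np.ndarray, k: int, exclude_self: bool = False) -> float:
    """Euclidean distance from ``query`` to its k-th closest reference point.

    ``k`` is 1-based on the ascending sort of distances. With ``exclude_self``
    one zero-distance copy of the query is removed from the reference set.
    """
    ref = np.atleast_2d(np.asarray(reference_set, dtype=float))
    d = np.sort(np.linalg.norm(ref - np.asarray(query, dtype=float), axis=1))
    if exclude_self:
        if d.size == 0 or d[0] != 0.0:
            raise ValueError("exclude_self requires the query to be in the reference set")
        d = d[1:]
    if k < 1 or k > d.size:
        raise ValueError(f"k={k} outside usable reference count {d.size}")
    return float(d[k - 1])


def density_profile(dataset, policy: KPolicy | None = None) -> DensityProfile:
    """Within- and between-class k-th NN distances for every instance.

    Within-class distances exclude the instance itself (an instance is not its
    own neighbor); between-class queries need no exclusion. Distances are
    Euclidean in the (normalized) input space.
    """
    policy = policy or KPolicy()
    dataset.require_trainable()
    k_pos, k_neg = policy.resolve(dataset.n_pos, dataset.n_neg)
    X, y = dataset.X, dataset.y
    pos, neg = X[y == 1], X[y == -1]
    trees = {1: cKDTree(pos), -1: cKDTree(neg)}
    own_k = {1: k_pos, -1: k_neg}

    d_within = np.empty(dataset.n)
    d_between = np.empty(dataset.n)
    for label in (1, -1):
        mask = y == label
        # own class: query k+1 neighbors, drop the zero self-distance
        dw, _ = trees[label].query(X[mask], k=own_k[label] + 1)
        d_within[mask] = dw[:, -1]
        db, _ = trees[-label].query(X[mask], k=own_k[-label])
        d_between[mask] = np.atleast_2d(db)[:, -1] if own_k[-label] > 1 else np.ravel(db)
    return DensityProfile(y.copy(), d_within, d_between, k_pos, k_neg)
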