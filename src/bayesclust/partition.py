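"""Set partitions of a sample, the Dirichlet-process partition prior, and
distances between clusterings.

A clustering of ``n`` observations is represented by an allocation vector
``z`` of cluster labels.  Internally every :class:`Partition` is stored in
canonical (order-of-appearance) form: observation 1 belongs to cluster 1 and
each new cluster label appears for the first time in increasing order along
the vector.  Two allocation vectors describe the same set partition exactly
when their canonical forms coincide, so equality, hashing and all distances
are label-permutation invariant by construction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Partition",
    "canonicalize",
    "dp_eppf_log",
    "binder_distance",
    "vi_distance",
    "contingency",
    "read_partition",
    "write_partition",
]


class Partition:
    """An unordered partition of ``{1, ..., n}`` into non-empty clusters.

    Parameters
    ----------
    labels : array-like of int, shape (n,)
        Cluster membership of each observation.  Arbitrary integer labels
        are accepted; they are relabelled to the canonical 1-based
        order-of-appearance form on construction.

    Attributes
    ----------
    labels : ndarray of int, shape (n,)
        Canonical 1-based allocation vector.
    n : int
        Number of observations.
    k : int
        Number of (non-empty) clusters.
    sizes : ndarray of int, shape (k,)
        Cluster sizes ``(n_1, ..., n_k)``; sums to ``n``.
    """

    __slots__ = ("labels", "n", "k", "sizes")

    def __init__(self, labels: Sequence[int] | np.ndarray):
        raw = np.asarray(labels)
        if raw.ndim != 1 or raw.size == 0:
            raise ValueError("labels must be a non-empty 1-d integer vector")
        if not np.issubdtype(raw.dtype, np.integer):
            intlike = np.asarray(raw, dtype=np.int64)
            if not np.array_equal(intlike, raw):
                raise ValueError("labels must be integers")
            raw = intlike
        canon, sizes = _canonical_labels(raw.astype(np.int64, copy=False))
        self.labels = canon
        self.n = int(canon.size)
        self.k = int(sizes.size)
        self.sizes = sizes
        self.labels.setflags(write=False)
        self.sizes.setflags(write=False)

    # -- identity -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        body = ",".join(map(str, self.labels[:12]))
        if self.n > 12:
            body += ",..."
        return f"Partition([{body}], n={self.n}, k={self.k})"

    def as_clusters(self) -> list[np.ndarray]:
        """Return the clusters as lists of 0-based observation indices."""
        return [np.flatnonzero(self.labels == j + 1) for j in range(self.k)]


def _canonical_labels(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order-of-appearance relabelling; returns (labels, sizes)."""
    canon = np.empty(raw.size, dtype=np.int64)
    mapping: dict[int, int] = {}
    sizes: list[int] = []
    for i, lab in enumerate(raw.tolist()):
        j = mapping.get(lab)
        if j is None:
            j = len(mapping) + 1
            mapping[lab] = j
            sizes.append(0)
        canon[i] = j
        sizes[j - 1] += 1
    return canon, np.asarray(sizes, dtype=np.int64)


def canonicalize(raw_labels: Sequence[int] | np.ndarray) -> Partition:
    """Relabel an allocation vector into canonical order-of-appearance form.

    Idempotent: ``canonicalize(p.labels) == p`` for any partition ``p``.
    """
    if isinstance(raw_labels, Partition):
        return raw_labels
    return Partition(raw_labels)


# ----------------------------------------------------------------------
# Dirichlet-process partition prior (exchangeable partition probability
# function): pi(z) = Gamma(alpha) / Gamma(alpha + n) * alpha^k * prod Gamma(n_j)
# ----------------------------------------------------------------------

def dp_eppf_log(z: Partition | Sequence[int], alpha: float) -> float:
    """Log prior probability of a partition under the Dirichlet process.

    The DP exchangeable partition probability function depends on the
    partition only through its cluster sizes, hence is invariant to cluster
    relabelling and to permutation of the observations.  Summing
    ``exp(dp_eppf_log)`` over every set partition of ``n`` items gives 1.

    Parameters
    ----------
    z : Partition or array-like
        The partition.
    alpha : float
        DP concentration parameter, ``alpha > 0``.  Larger values put more
        prior mass on partitions with many clusters.
    """
    if alpha <= 0 or not np.isfinite(alpha):
        raise ValueError(f"alpha must be positive, got {alpha}")
    z = canonicalize(z)
    return float(
        gammaln(alpha)
        - gammaln(alpha + z.n)
        + z.k * np.log(alpha)
        + gammaln(z.sizes).sum()
    )


# ----------------------------------------------------------------------
# Distances between partitions
# ----------------------------------------------------------------------

def contingency(z1: Partition | Sequence[int], z2: Partition | Sequence[int]) -> np.ndarray:
    """k1 x k2 contingency table of joint cluster counts."""
    z1, z2 = canonicalize(z1), canonicalize(z2)
    if z1.n != z2.n:
        raise ValueError(f"partitions have different lengths: {z1.n} vs {z2.n}")
    table = np.zeros((z1.k, z2.k), dtype=np.int64)
    np.add.at(table, (z1.labels - 1, z2.labels - 1), 1)
    return table


def binder_distance(
    z1: Partition | Sequence[int],
    z2: Partition | Sequence[int],
    a: float = 1.0,
    b: float = 1.0,
) -> float:
    """Binder's loss between two partitions: weighted pairwise disagreements.

    Counts the observation pairs on which the partitions disagree about
    co-clustering; with unit weights (the default) this is the symmetric
    pair-count ``sum_{i<i'} [1(z1_i = z1_i') - 1(z2_i = z2_i')]^2``.  ``a``
    weights pairs split by ``z2`` but joined by ``z1``; ``b`` the reverse.
    Zero exactly when the two partitions are equal up to relabelling.
    """
    table = contingency(z1, z2)
    same_both = _pairs(table).sum()
    same_1 = _pairs(table.sum(axis=1)).sum()
    same_2 = _pairs(table.sum(axis=0)).sum()
    return float(a * (same_1 - same_both) + b * (same_2 - same_both))


def _pairs(counts: np.ndarray) -> np.ndarray:
    c = counts.astype(np.float64)
    return c * (c - 1.0) / 2.0


def vi_distance(
    z1: Partition | Sequence[int],
    z2: Partition | Sequence[int],
    base: float | None = None,
) -> float:
    """Variation of information between two partitions.

    ``VI(z1, z2) = H(z1) + H(z2) - 2 I(z1, z2)`` with entropies computed
    from empirical cluster frequencies.  A true metric on set partitions
    (symmetric, triangle inequality, zero only at equality).  Natural
    logarithms by default (nats); pass ``base=2`` for bits.
    """
    table = contingency(z1, z2).astype(np.float64)
    n = table.sum()
    p12 = table / n
    p1 = p12.sum(axis=1)
    p2 = p12.sum(axis=0)
    h1 = -np.sum(p1 * np.log(p1, where=p1 > 0, out=np.zeros_like(p1)))
    h2 = -np.sum(p2 * np.log(p2, where=p2 > 0, out=np.zeros_like(p2)))
    mask = p12 > 0
    mi = np.sum(p12[mask] * np.log(p12[mask] / np.outer(p1, p2)[mask]))
    vi = h1 + h2 - 2.0 * mi
    if base is not None:
        vi /= np.log(base)
    # round-off from the entropy sums can leave a tiny residual at equality;
    # genuinely distinct partitions of n items are O(log(n)/n) apart, so
    # snapping far below that keeps the "zero iff equal" metric property
    return float(vi) if vi > 1e-12 else 0.0


# ----------------------------------------------------------------------
# Serialization: single-column integer CSV, one label per row
# ----------------------------------------------------------------------

def write_partition(path, z: Partition | Sequence[int]) -> None:
    z = canonicalize(z)
    np.savetxt(path, z.labels, fmt="%d")


def read_partition(path) -> Partition:
    return Partition(np.loadtxt(path, dtype=np.int64, ndmin=1))
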