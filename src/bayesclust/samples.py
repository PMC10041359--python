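"""Container for an ordered collection of posterior partition draws."""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np

from .partition import Partition

__all__ = ["PartitionSamples"]


class PartitionSamples:
    """Posterior draws of a partition of ``n`` observations.

    Parameters
    ----------
    draws : ndarray of int, shape (M, n)
        One allocation vector per row.  Rows are canonicalized
        (order-of-appearance labels, 1-based) on construction.
    meta : mapping, optional
        Sampler metadata (seed, iteration counts, hyperparameters, ...).
    """

    def __init__(self, draws: np.ndarray | Sequence[Sequence[int]], meta: Mapping | None = None):
        draws = np.atleast_2d(np.asarray(draws, dtype=np.int64))
        if draws.size == 0:
            raise ValueError("at least one partition draw is required")
        self.draws = _canonicalize_rows(draws)
        self.draws.setflags(write=False)
        self.meta: dict = dict(meta or {})

    @property
    def n(self) -> int:
        return self.draws.shape[1]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def __len__(self) -> int:
        return self.n_draws

    def __iter__(self) -> Iterator[Partition]:
        for row in self.draws:
            yield Partition(row)

    def __getitem__(self, m: int) -> Partition:
        return Partition(self.draws[m])

    def k_per_draw(self) -> np.ndarray:
        """Number of clusters in each draw."""
        return self.draws.max(axis=1)

    def unique_draws(self) -> np.ndarray:
        """Deduplicated canonical draws, in order of first appearance."""
        _, idx = np.unique(self.draws, axis=0, return_index=True)
        return self.draws[np.sort(idx)]

    # -- plain-text IO: one draw per row, comma-separated ----------------
    def save(self, path) -> None:
        np.savetxt(path, self.draws, fmt="%d", delimiter=",")

    @classmethod
    def load(cls, path, meta: Mapping | None = None) -> "PartitionSamples":
        return cls(np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2), meta=meta)

    def __repr__(self) -> str:
        return f"PartitionSamples(n_draws={self.n_draws}, n={self.n})"


def _canonicalize_rows(draws: np.ndarray) -> np.ndarray:
    if draws.min() >= 0 and draws.max() <= draws.shape[1]:
        # fast path for sampler output (small non-negative labels)
        from ._gibbs import canonicalize_rows

        return canonicalize_rows(draws)
    out = np.empty_like(draws)
    for r in range(draws.shape[0]):
        row = draws[r]
        mapping: dict[int, int] = {}
        orow = out[r]
        for i in range(row.size):
            lab = row[i]
            j = mapping.get(lab)
            if j is None:
                j = len(mapping) + 1
                mapping[lab] = j
            orow[i] = j
    return out
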