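"""Shared fixtures and independent oracles for the test suite.

The oracles here (set-partition enumeration, brute-force pair counting,
entropy-based VI) are deliberately written from first principles, separate
from the library's implementations, so they can serve as ground truth.
"""

import itertools
import math

import numpy as np
import pytest


def set_partitions(n):
    """All set partitions of {0, ..., n-1} as canonical 0-based label lists,
    enumerated via restricted growth strings."""

    def rec(prefix, mx):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(mx + 2):
            yield from rec(prefix + [lab], max(mx, lab))

    yield from rec([0], 0)


def brute_binder(z1, z2):
    """Pairwise co-clustering disagreement count by direct enumeration."""
    z1, z2 = np.asarray(z1), np.asarray(z2)
    n = z1.size
    count = 0
    for i, j in itertools.combinations(range(n), 2):
        count += (z1[i] == z1[j]) != (z2[i] == z2[j])
    return float(count)


def brute_vi(z1, z2):
    """Variation of information from explicit entropies (nats)."""
    z1, z2 = np.asarray(z1), np.asarray(z2)
    n = z1.size

    def entropy(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    joint = [(a, b) for a, b in zip(z1.tolist(), z2.tolist())]
    _, jc = np.unique(joint, axis=0, return_counts=True)
    pj = jc / n
    h_joint = -np.sum(pj * np.log(pj))
    h1, h2 = entropy(z1), entropy(z2)
    mi = h1 + h2 - h_joint
    return max(h1 + h2 - 2 * mi, 0.0)


def enumerated_posterior(X, prior, alpha, log_posterior_partition):
    """Exact posterior over all set partitions of the rows of X."""
    parts = [np.asarray(p) + 1 for p in set_partitions(X.shape[0])]
    logs = np.array([log_posterior_partition(p, X, prior, alpha) for p in parts])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return parts, probs


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
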