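"""Synthetic data generators with known ground-truth clusterings.

Provides the two benchmark designs used in the estimator-comparison study —
a standard normal sample (whose true clustering is a single cluster, the
classic setting in which the Dirichlet-process posterior on the number of
clusters is inconsistent) and a uniform sample on the unit disk (a
misspecified target for a Gaussian mixture) — plus generic finite Gaussian
mixtures with labelled components.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition import Partition

__all__ = [
    "MixtureSpec",
    "gen_standard_normal",
    "gen_uniform_disk",
    "gen_gaussian_mixture",
    "read_dataset",
    "write_dataset",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class MixtureSpec:
    """A finite Gaussian mixture: weights, component means and covariances.

    ``means[j]`` is a length-d vector and ``covariances[j]`` a d x d
    symmetric positive-definite matrix (scalars/1-vectors accepted for
    d = 1).  Weights must be non-negative and sum to one.
    """

    weights: tuple[float, ...]
    means: tuple[np.ndarray, ...] = field(repr=False)
    covariances: tuple[np.ndarray, ...] = field(repr=False)

    def __init__(self, weights, means, covariances):
        w = np.asarray(weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty vector")
        if np.any(w < 0) or abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must be non-negative and sum to 1, got {w}")
        if not (len(means) == len(covariances) == w.size):
            raise ValueError("weights, means and covariances must have equal length")
        mus = tuple(np.atleast_1d(np.asarray(m, dtype=np.float64)) for m in means)
        d = mus[0].size
        if any(m.size != d for m in mus):
            raise ValueError("all component means must have the same dimension")
        covs = []
        for S in covariances:
            S = np.asarray(S, dtype=np.float64)
            if S.ndim == 0:
                S = S.reshape(1, 1)
            elif S.ndim == 1:
                S = np.diag(S)
            if S.shape != (d, d) or not np.allclose(S, S.T):
                raise ValueError("covariances must be symmetric d x d matrices")
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError("covariances must be positive definite")
            covs.append(S)
        object.__setattr__(self, "weights", tuple(w.tolist()))
        object.__setattr__(self, "means", mus)
        object.__setattr__(self, "covariances", tuple(covs))

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means[0].size


def _check_n(n: int) -> int:
    n = int(n)
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return n


def gen_standard_normal(n: int, seed: int) -> np.ndarray:
    """n i.i.d. draws from N(0, 1), returned as an (n, 1) matrix.

    The true clustering of this design is a single cluster.
    """
    n = _check_n(n)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 1))


def gen_uniform_disk(n: int, seed: int, boundary_only: bool = False) -> np.ndarray:
    """n points uniform on the closed unit disk in the plane, shape (n, 2).

    Sampling uses the inverse-CDF radius transform ``r = sqrt(u)`` with a
    uniform angle, which is exact for the solid disk.  With
    ``boundary_only=True`` points are placed on the unit circle itself
    (``r = 1``); the solid disk is the default.
    """
    n = _check_n(n)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = 1.0 if boundary_only else np.sqrt(rng.uniform(0.0, 1.0, size=n))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def gen_gaussian_mixture(
    n: int, spec: MixtureSpec, seed: int
) -> tuple[np.ndarray, Partition]:
    """Sample from a finite Gaussian mixture together with its true labels.

    Each row's component is drawn from ``Categorical(weights)`` and the
    observation from the corresponding Gaussian.  Returns ``(X, truth)``
    where ``truth`` is the canonical ground-truth partition.
    """
    n = _check_n(n)
    if not isinstance(spec, MixtureSpec):
        spec = MixtureSpec(*spec)
    rng = np.random.default_rng(seed)
    comps = rng.choice(spec.n_components, size=n, p=np.asarray(spec.weights))
    X = np.empty((n, spec.d))
    for j in range(spec.n_components):
        idx = np.flatnonzero(comps == j)
        if idx.size:
            X[idx] = rng.multivariate_normal(
                spec.means[j], spec.covariances[j], size=idx.size
            )
    return X, Partition(comps + 1)


# ----------------------------------------------------------------------
# Plain-text IO: headerless delimited matrix, one observation per row
# ----------------------------------------------------------------------

def write_dataset(path, X: np.ndarray, delimiter: str = ",") -> None:
    np.savetxt(path, np.atleast_2d(X), delimiter=delimiter, fmt="%.17g")


def read_dataset(path, delimiter: str = ",") -> np.ndarray:
    X = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite values in dataset {path}")
    return X
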