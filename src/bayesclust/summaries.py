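"""Posterior summarization: similarity matrix, point-estimate partitions
under 0-1 / Binder / variation-of-information losses, and credible balls.

Point estimation follows the decision-theoretic recipe: among a candidate
set consisting of the (deduplicated) MCMC draws together with every cut of
a hierarchical clustering built on ``1 - posterior similarity``, pick the
candidate minimizing the posterior expected loss, then refine it by greedy
search over single-observation reassignments and cluster merges.

The expected Binder loss of a candidate is an exact linear function of the
posterior similarity matrix (PSM).  For the VI the default objective is the
Jensen ("PSM lower bound") surrogate computed from the PSM alone; the exact
Monte-Carlo average over draws is available as ``mode="exact-average"`` and
is the honest but O(M) alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from . import _gibbs
from .partition import Partition, binder_distance, canonicalize, vi_distance
from .samples import PartitionSamples

__all__ = [
    "EstimatorResult",
    "CredibleBall",
    "posterior_similarity",
    "expected_binder",
    "expected_vi",
    "candidate_set",
    "greedy_search",
    "estimate",
    "marginal_mode_k",
    "credible_ball",
]


@dataclass(frozen=True)
class EstimatorResult:
    """A point-estimate partition with its loss and objective value."""

    partition: Partition
    loss_name: str
    objective: float

    @property
    def k(self) -> int:
        return self.partition.k


@dataclass(frozen=True)
class CredibleBall:
    """Smallest metric ball around ``center`` holding >= ``level`` of the
    posterior draws; ``radius`` is the ball's radius in the chosen metric."""

    center: Partition
    metric: str
    level: float
    radius: float


# ----------------------------------------------------------------------
# Posterior similarity
# ----------------------------------------------------------------------

def posterior_similarity(samples: PartitionSamples) -> np.ndarray:
    """n x n matrix of pairwise co-clustering frequencies across draws.

    Entry (i, j) is the fraction of draws in which observations i and j
    share a cluster; symmetric with unit diagonal.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one draw")
    out = np.zeros((samples.n, samples.n))
    _gibbs.psm_accumulate(samples.draws, out)
    out /= samples.n_draws
    return out


def expected_binder(candidate: Partition | np.ndarray, psm: np.ndarray) -> float:
    """Posterior-expected Binder loss of a candidate, exactly from the PSM.

    Equals the Monte-Carlo average of ``binder_distance(candidate, draw)``
    over the draws that produced ``psm`` (an identity, not an approximation).
    """
    z = canonicalize(candidate)
    psm = np.asarray(psm)
    if psm.shape != (z.n, z.n):
        raise ValueError("candidate and PSM sizes do not match")
    same = z.labels[:, None] == z.labels[None, :]
    iu = np.triu_indices(z.n, k=1)
    p = psm[iu]
    s = same[iu]
    return float(np.sum(np.where(s, 1.0 - p, p)))


def expected_vi(
    candidate: Partition | np.ndarray,
    samples: PartitionSamples | None = None,
    psm: np.ndarray | None = None,
    mode: str = "psm-lower-bound",
) -> float:
    """Posterior-expected VI of a candidate (nats).

    ``mode="exact-average"`` returns the mean VI distance to the draws;
    ``mode="psm-lower-bound"`` returns the Jensen surrogate computed from
    the PSM alone (log and expectation swapped inside the entropy terms),
    which is the quantity the VI point estimate minimizes by default.
    """
    z = canonicalize(candidate)
    if mode == "exact-average":
        if samples is None:
            raise ValueError("exact-average mode requires the draws")
        return float(np.mean([vi_distance(z.labels, row) for row in samples.draws]))
    if mode != "psm-lower-bound":
        raise ValueError(f"unknown mode {mode!r}")
    if psm is None:
        if samples is None:
            raise ValueError("psm-lower-bound mode requires a PSM or the draws")
        psm = posterior_similarity(samples)
    psm = np.asarray(psm)
    if psm.shape != (z.n, z.n):
        raise ValueError("candidate and PSM sizes do not match")
    logr = np.log(psm.sum(axis=1))
    return float(_gibbs.vilb_scores(z.labels[None, :], psm, logr)[0])


# ----------------------------------------------------------------------
# Candidate set: MCMC draws plus hierarchical-clustering cuts on 1 - PSM
# ----------------------------------------------------------------------

def _candidate_rows(
    samples: PartitionSamples, psm: np.ndarray, linkage: str = "average"
) -> np.ndarray:
    n = samples.n
    rows = [samples.unique_draws()]
    if n > 1:
        diss = 1.0 - psm
        np.fill_diagonal(diss, 0.0)
        cond = squareform(diss, checks=False)
        Z = scipy_linkage(np.maximum(cond, 0.0), method=linkage)
        cuts = cut_tree(Z, n_clusters=np.arange(1, n + 1)).T + 1
        rows.append(_gibbs.canonicalize_rows(np.ascontiguousarray(cuts, dtype=np.int64)))
    # tied merge heights can make cut_tree skip cut levels; the dendrogram
    # extremes are part of the contract, so guarantee them
    rows.append(np.ones((1, n), dtype=np.int64))
    rows.append(np.arange(1, n + 1, dtype=np.int64)[None, :])
    allrows = np.vstack(rows)
    # deterministic order: lexicographic on the canonical labels
    order = np.lexsort(allrows.T[::-1])
    allrows = allrows[order]
    keep = np.ones(allrows.shape[0], dtype=bool)
    keep[1:] = np.any(allrows[1:] != allrows[:-1], axis=1)
    return allrows[keep]


def candidate_set(
    samples: PartitionSamples, psm: np.ndarray | None = None, linkage: str = "average"
) -> list[Partition]:
    """Deduplicated, canonical candidate partitions for point estimation.

    The union of the MCMC draws and the dendrogram cuts (k = 1 .. n) of a
    hierarchical clustering with dissimilarity ``1 - PSM``; always contains
    the one-cluster and the all-singleton partitions.
    """
    if psm is None:
        psm = posterior_similarity(samples)
    return [Partition(row) for row in _candidate_rows(samples, psm, linkage)]


# ----------------------------------------------------------------------
# Incremental objective states for the greedy search
# ----------------------------------------------------------------------
# Each state tracks a current partition (0-based labels, clusters 0..k-1)
# and evaluates, in O(n)-ish time, the change of its objective under the
# greedy neighbourhood: move one observation to any cluster or to a new
# singleton, or merge two clusters.  Column k of move_deltas() is the
# new-singleton move; unavailable moves are +inf.

class _ObjectiveState:
    def __init__(self, labels0: np.ndarray):
        self.labels = labels0.astype(np.int64).copy()
        self.n = self.labels.size
        self.k = int(self.labels.max()) + 1
        self.counts = np.zeros(self.n, dtype=np.int64)
        np.add.at(self.counts, self.labels, 1)

    def value(self) -> float:
        raise NotImplementedError

    def move_deltas(self) -> np.ndarray:
        raise NotImplementedError

    def merge_deltas(self) -> np.ndarray:
        raise NotImplementedError

    # -- bookkeeping -----------------------------------------------------
    def apply_move(self, i: int, t: int) -> None:
        A = int(self.labels[i])
        if t == A:
            return
        new_cluster = t == self.k
        self._move_stats(i, A, t)
        self.labels[i] = t
        self.counts[A] -= 1
        self.counts[t] += 1
        if new_cluster:
            self.k += 1
        if self.counts[A] == 0:
            self._compact(A)

    def apply_merge(self, a: int, b: int) -> None:
        self._merge_stats(a, b)
        self.labels[self.labels == b] = a
        self.counts[a] += self.counts[b]
        self.counts[b] = 0
        self._compact(b)

    def _compact(self, hole: int) -> None:
        last = self.k - 1
        if hole != last:
            self.labels[self.labels == last] = hole
            self.counts[hole] = self.counts[last]
            self._swap_stats(hole, last)
        self.counts[last] = 0
        self.k -= 1

    # subclass hooks
    def _move_stats(self, i: int, src: int, dst: int) -> None:  # pragma: no cover
        pass

    def _swap_stats(self, dst: int, src: int) -> None:  # pragma: no cover
        pass

    def _merge_stats(self, a: int, b: int) -> None:  # pragma: no cover
        pass


class _BinderState(_ObjectiveState):
    """Expected Binder loss; S[:, c] = sum_{j in c} (1 - 2 psm)_ij."""

    def __init__(self, labels0, psm):
        super().__init__(labels0)
        self.Q = 1.0 - 2.0 * np.asarray(psm)
        iu = np.triu_indices(self.n, k=1)
        self.const = float(np.asarray(psm)[iu].sum())
        self.S = np.zeros((self.n, self.n))
        for c in range(self.k):
            self.S[:, c] = self.Q[:, self.labels == c].sum(axis=1)

    def value(self) -> float:
        idx = np.arange(self.n)
        within = 0.5 * (self.S[idx, self.labels].sum() + self.n)
        return self.const + float(within)

    def move_deltas(self) -> np.ndarray:
        idx = np.arange(self.n)
        a = self.S[idx, self.labels] + 1.0
        D = np.empty((self.n, self.k + 1))
        D[:, : self.k] = self.S[:, : self.k] - a[:, None]
        D[:, self.k] = -a
        D[idx, self.labels] = np.inf
        D[self.counts[self.labels] == 1, self.k] = np.inf
        return D

    def merge_deltas(self) -> np.ndarray:
        M = np.zeros((self.k, self.k))
        np.add.at(M, self.labels, self.S[:, : self.k])
        out = np.full((self.k, self.k), np.inf)
        iu = np.triu_indices(self.k, k=1)
        out[iu] = M[iu]
        return out

    def _move_stats(self, i, src, dst):
        self.S[:, src] -= self.Q[:, i]
        self.S[:, dst] += self.Q[:, i]

    def _swap_stats(self, dst, src):
        self.S[:, dst] = self.S[:, src]
        self.S[:, src] = 0.0

    def _merge_stats(self, a, b):
        self.S[:, a] += self.S[:, b]
        self.S[:, b] = 0.0


class _VILBState(_ObjectiveState):
    """PSM lower bound of the expected VI; q[:, c] = sum_{j in c} psm_ij."""

    def __init__(self, labels0, psm):
        super().__init__(labels0)
        self.P = np.asarray(psm)
        self.logr = np.log(self.P.sum(axis=1))
        self.q = np.zeros((self.n, self.n))
        for c in range(self.k):
            self.q[:, c] = self.P[:, self.labels == c].sum(axis=1)

    def _own_terms(self) -> np.ndarray:
        idx = np.arange(self.n)
        return np.log(self.counts[self.labels]) - 2.0 * np.log(self.q[idx, self.labels])

    def value(self) -> float:
        return float((self._own_terms() + self.logr).sum() / self.n)

    def move_deltas(self) -> np.ndarray:
        n, k = self.n, self.k
        lab = self.labels
        m = self.counts[:k].astype(np.float64)
        own = self._own_terms()
        qown = self.q[np.arange(n), lab]
        D = np.full((n, k + 1), np.inf)
        log_m = np.log(m)
        log_m1 = np.log(m + 1.0)
        for i in range(n):
            A = lab[i]
            pi = self.P[:, i]
            mA = m[A]
            if mA > 1:
                memA = np.flatnonzero(lab == A)
                memA = memA[memA != i]
                qA = self.q[memA, A]
                remove = float(
                    ((math.log(mA - 1.0) - 2.0 * np.log(qA - pi[memA]))
                     - (math.log(mA) - 2.0 * np.log(qA))).sum()
                )
            else:
                remove = 0.0
            # gain of each target cluster from absorbing i
            t = log_m1[lab] - log_m[lab] - 2.0 * (np.log(qown + pi) - np.log(qown))
            add_core = np.bincount(lab, weights=t, minlength=k)
            self_new = log_m1 - 2.0 * np.log(self.q[i, :k] + 1.0)
            row = remove + add_core + self_new - own[i]
            row[A] = np.inf
            D[i, :k] = row
            if mA > 1:
                D[i, k] = remove - own[i]  # new singleton: log 1 - 2 log 1 = 0
        return D / n

    def merge_deltas(self) -> np.ndarray:
        k = self.k
        lab = self.labels
        cur = np.bincount(lab, weights=self._own_terms(), minlength=k)
        out = np.full((k, k), np.inf)
        for a in range(k):
            mem_a = np.flatnonzero(lab == a)
            for b in range(a + 1, k):
                mem_b = np.flatnonzero(lab == b)
                mab = float(self.counts[a] + self.counts[b])
                new = (
                    (math.log(mab) - 2.0 * np.log(self.q[mem_a, a] + self.q[mem_a, b])).sum()
                    + (math.log(mab) - 2.0 * np.log(self.q[mem_b, a] + self.q[mem_b, b])).sum()
                )
                out[a, b] = (new - cur[a] - cur[b]) / self.n
        return out

    def _move_stats(self, i, src, dst):
        self.q[:, src] -= self.P[:, i]
        self.q[:, dst] += self.P[:, i]

    def _swap_stats(self, dst, src):
        self.q[:, dst] = self.q[:, src]
        self.q[:, src] = 0.0

    def _merge_stats(self, a, b):
        self.q[:, a] += self.q[:, b]
        self.q[:, b] = 0.0


class _MAPState(_ObjectiveState):
    """Negative unnormalized log posterior of the DP Gaussian mixture."""

    def __init__(self, labels0, data, prior, alpha):
        super().__init__(labels0)
        self.X = np.ascontiguousarray(np.atleast_2d(np.asarray(data, dtype=np.float64)))
        n, d = self.X.shape
        self.d = d
        self.prior = prior
        self.alpha = float(alpha)
        self.log_alpha = math.log(alpha)
        self.mu0 = np.ascontiguousarray(prior.mu0)
        self.L0 = np.ascontiguousarray(prior.delta2)
        self.const_m = _gibbs._const_table(
            n, d, prior.c, prior.nu, _gibbs._logdet_chol(self.L0)
        )
        self.sums = np.zeros((n, d))
        self.sqs = np.zeros((n, d, d))
        self.outers = self.X[:, :, None] * self.X[:, None, :]
        np.add.at(self.sums, self.labels, self.X)
        np.add.at(self.sqs, self.labels, self.outers)
        self.clogml = np.zeros(n)
        for c in range(self.k):
            self.clogml[c] = self._lml(self.counts[c], self.sums[c], self.sqs[c])

    def _lml(self, m, s, SS):
        return _gibbs._logml(
            m, s, SS, self.mu0, self.prior.c, self.L0, self.prior.nu, self.const_m, self.d
        )

    def value(self) -> float:
        k = self.k
        eppf = (
            gammaln(self.alpha)
            - gammaln(self.alpha + self.n)
            + k * self.log_alpha
            + gammaln(self.counts[:k]).sum()
        )
        return float(-(eppf + self.clogml[:k].sum()))

    def move_deltas(self) -> np.ndarray:
        n, k = self.n, self.k
        D = np.full((n, k + 1), np.inf)
        lg = gammaln(np.arange(n + 2))
        for i in range(n):
            A = int(self.labels[i])
            mA = int(self.counts[A])
            x = self.X[i]
            xo = self.outers[i]
            lml_rm = self._lml(mA - 1, self.sums[A] - x, self.sqs[A] - xo)
            d_rm = (lml_rm - self.clogml[A]) + (lg[mA - 1] - lg[mA] if mA > 1 else -lg[mA])
            if mA == 1:
                d_rm -= self.log_alpha  # cluster A disappears
            for B in range(k):
                if B == A:
                    continue
                mB = int(self.counts[B])
                lml_add = self._lml(mB + 1, self.sums[B] + x, self.sqs[B] + xo)
                d_add = (lml_add - self.clogml[B]) + (lg[mB + 1] - lg[mB])
                D[i, B] = -(d_rm + d_add)
            if mA > 1:
                lml_new = self._lml(1, x, xo)
                D[i, k] = -(d_rm + self.log_alpha + lml_new)
        return D

    def merge_deltas(self) -> np.ndarray:
        k = self.k
        lg = gammaln(np.arange(self.n + 1))
        out = np.full((k, k), np.inf)
        for a in range(k):
            for b in range(a + 1, k):
                ma, mb = int(self.counts[a]), int(self.counts[b])
                lml_ab = self._lml(
                    ma + mb, self.sums[a] + self.sums[b], self.sqs[a] + self.sqs[b]
                )
                d = (
                    lml_ab
                    - self.clogml[a]
                    - self.clogml[b]
                    + lg[ma + mb]
                    - lg[ma]
                    - lg[mb]
                    - self.log_alpha
                )
                out[a, b] = -d
        return out

    def _move_stats(self, i, src, dst):
        x, xo = self.X[i], self.outers[i]
        self.sums[src] -= x
        self.sqs[src] -= xo
        self.sums[dst] += x
        self.sqs[dst] += xo
        self.clogml[src] = self._lml(self.counts[src] - 1, self.sums[src], self.sqs[src])
        self.clogml[dst] = self._lml(self.counts[dst] + 1, self.sums[dst], self.sqs[dst])

    def _swap_stats(self, dst, src):
        self.sums[dst] = self.sums[src]
        self.sqs[dst] = self.sqs[src]
        self.clogml[dst] = self.clogml[src]
        self.sums[src] = 0.0
        self.sqs[src] = 0.0
        self.clogml[src] = 0.0

    def _merge_stats(self, a, b):
        self.sums[a] += self.sums[b]
        self.sqs[a] += self.sqs[b]
        self.clogml[a] = self._lml(
            self.counts[a] + self.counts[b], self.sums[a], self.sqs[a]
        )
        self.sums[b] = 0.0
        self.sqs[b] = 0.0
        self.clogml[b] = 0.0


class _CallableState(_ObjectiveState):
    """Brute-force adapter evaluating an arbitrary partition objective."""

    def __init__(self, labels0, fn):
        super().__init__(labels0)
        self.fn = fn

    def value(self) -> float:
        return float(self.fn(Partition(self.labels + 1)))

    def _try(self, labels) -> float:
        return float(self.fn(Partition(labels + 1)))

    def move_deltas(self) -> np.ndarray:
        base = self.value()
        D = np.full((self.n, self.k + 1), np.inf)
        for i in range(self.n):
            A = self.labels[i]
            for t in range(self.k + 1):
                if t == A or (t == self.k and self.counts[A] == 1):
                    continue
                trial = self.labels.copy()
                trial[i] = t
                D[i, t] = self._try(trial) - base
        return D

    def merge_deltas(self) -> np.ndarray:
        base = self.value()
        out = np.full((self.k, self.k), np.inf)
        for a in range(self.k):
            for b in range(a + 1, self.k):
                trial = self.labels.copy()
                trial[trial == b] = a
                out[a, b] = self._try(trial) - base
        return out


def _run_greedy(state: _ObjectiveState, max_moves: int) -> None:
    for _ in range(max_moves):
        D = state.move_deltas()
        M = state.merge_deltas()
        im = int(np.argmin(D))
        best_move = D.flat[im]
        jm = int(np.argmin(M))
        best_merge = M.flat[jm] if M.size else np.inf
        tol = -1e-9 * (1.0 + abs(state.value()))
        if min(best_move, best_merge) >= tol:
            break
        if best_move <= best_merge:
            i, t = divmod(im, state.k + 1)
            state.apply_move(i, t)
        else:
            a, b = divmod(jm, state.k)
            state.apply_merge(a, b)


def greedy_search(
    init: Partition | np.ndarray,
    objective,
    max_sweeps: int = 50,
) -> Partition:
    """Greedy descent of ``objective`` over partitions from ``init``.

    The neighbourhood consists of single-observation reassignments (to any
    existing cluster or a new singleton) and merges of two clusters; the
    best objective-decreasing neighbour is accepted until a local optimum
    or the sweep limit is reached.  ``objective`` is any callable mapping a
    :class:`Partition` to a real number; the returned partition never has a
    larger objective than ``init``.
    """
    z = canonicalize(init)
    state = _CallableState(z.labels - 1, objective)
    _run_greedy(state, max_moves=max_sweeps * z.n)
    return Partition(state.labels + 1)


# ----------------------------------------------------------------------
# Point estimation
# ----------------------------------------------------------------------

_LOSS_ALIASES = {
    "map": "zero-one",
    "zero-one": "zero-one",
    "0-1": "zero-one",
    "binder": "binder",
    "vi": "vi",
}


def estimate(
    samples: PartitionSamples,
    loss_name: str,
    psm: np.ndarray | None = None,
    data: np.ndarray | None = None,
    prior=None,
    alpha: float | None = None,
    mode: str = "psm-lower-bound",
    linkage: str = "average",
    max_sweeps: int = 50,
    candidates=None,
) -> EstimatorResult:
    """Decision-theoretic point estimate of the clustering.

    Minimizes the loss-matched objective over the candidate set (draws plus
    hierarchical cuts of ``1 - PSM``) and refines the best candidate by
    greedy search:

    - ``"zero-one"`` (MAP): negative unnormalized log posterior; requires
      ``data``, ``prior`` and ``alpha``.
    - ``"binder"``: posterior-expected Binder loss, exact from the PSM.
    - ``"vi"``: PSM lower bound of the expected VI (default) or the exact
      Monte-Carlo average with ``mode="exact-average"``.

    Ties are broken toward the lexicographically first canonical candidate.
    """
    try:
        loss = _LOSS_ALIASES[loss_name]
    except KeyError:
        raise ValueError(f"unknown loss {loss_name!r}") from None
    if psm is None:
        psm = posterior_similarity(samples)
    if candidates is None:
        rows = _candidate_rows(samples, psm, linkage)
    elif isinstance(candidates, np.ndarray):
        rows = candidates
    else:
        rows = np.vstack([canonicalize(c).labels for c in candidates])
    labels0 = rows - 1

    if loss == "binder":
        Q = 1.0 - 2.0 * psm
        const = float(psm[np.triu_indices(samples.n, k=1)].sum())
        scores = _gibbs.binder_scores(rows, Q, const)
        make_state = lambda z0: _BinderState(z0, psm)  # noqa: E731
    elif loss == "vi":
        if mode == "psm-lower-bound":
            logr = np.log(psm.sum(axis=1))
            scores = _gibbs.vilb_scores(rows, psm, logr)
            make_state = lambda z0: _VILBState(z0, psm)  # noqa: E731
        elif mode == "exact-average":
            fn = lambda p: float(  # noqa: E731
                np.mean([vi_distance(p.labels, row) for row in samples.draws])
            )
            scores = np.array([fn(Partition(row)) for row in rows])
            make_state = lambda z0: _CallableState(z0, fn)  # noqa: E731
        else:
            raise ValueError(f"unknown VI mode {mode!r}")
    else:  # zero-one / MAP
        if data is None or prior is None or alpha is None:
            raise ValueError("the MAP estimate requires data, prior and alpha")
        from .dpmixture import log_posterior_partition

        scores = np.array(
            [-log_posterior_partition(row, data, prior, alpha) for row in rows]
        )
        make_state = lambda z0: _MAPState(z0, data, prior, alpha)  # noqa: E731

    best = int(np.argmin(scores))
    state = make_state(labels0[best])
    _run_greedy(state, max_moves=max_sweeps * samples.n)
    part = Partition(state.labels + 1)
    return EstimatorResult(partition=part, loss_name=loss, objective=float(state.value()))


def marginal_mode_k(samples: PartitionSamples) -> int:
    """Mode of the marginal posterior on the number of clusters.

    Ties are broken toward the smaller k.
    """
    counts = np.bincount(samples.k_per_draw())
    return int(np.argmax(counts))


def credible_ball(
    samples: PartitionSamples,
    center: Partition | np.ndarray,
    metric: str = "vi",
    level: float = 0.95,
) -> CredibleBall:
    """Credible ball of posterior partitions around a point estimate.

    The radius is the smallest distance such that at least ``level`` of the
    draws lie within it, i.e. the ``ceil(level * M)``-th order statistic of
    the draw-to-center distances.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    center = canonicalize(center)
    if metric == "vi":
        dist = vi_distance
    elif metric == "binder":
        dist = binder_distance
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = np.sort([dist(center.labels, row) for row in samples.draws])
    m = d.size
    radius = float(d[min(math.ceil(level * m), m) - 1])
    return CredibleBall(center=center, metric=metric, level=level, radius=radius)
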