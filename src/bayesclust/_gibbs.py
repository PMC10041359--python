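"""Numba kernels: collapsed Gibbs sampling for the DP Gaussian mixture.

The sampler is a marginal (Neal algorithm-3 style) Gibbs scan over the
allocation vector, with cluster parameters integrated out under the
conjugate normal-inverse-Wishart base measure (normal-inverse-gamma when
d = 1).  All per-cluster quantities are sufficient statistics
``(m, sum, sum of outer products)``; predictive weights are computed as
marginal-likelihood differences, in log space throughout.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_chain", "canonicalize_rows"]


@njit(cache=True)
def _logdet_chol(A):
    """Log-determinant of a small SPD matrix via manual Cholesky."""
    d = A.shape[0]
    L = np.zeros((d, d))
    ld = 0.0
    for i in range(d):
        for j in range(i + 1):
            s = A[i, j]
            for t in range(j):
                s -= L[i, t] * L[j, t]
            if i == j:
                L[i, i] = math.sqrt(s)
                ld += math.log(L[i, i])
            else:
                L[i, j] = s / L[j, j]
    return 2.0 * ld


@njit(cache=True)
def _mvlgamma(a, d):
    out = 0.25 * d * (d - 1) * math.log(math.pi)
    for i in range(d):
        out += math.lgamma(a - 0.5 * i)
    return out


@njit(cache=True)
def _logml(m, s, SS, mu0, kappa0, Lambda0, nu0, const_m, d):
    """Log marginal likelihood of one cluster from its sufficient stats."""
    if m == 0:
        return 0.0
    Lam = np.empty((d, d))
    coef = kappa0 * m / (kappa0 + m)
    for a in range(d):
        for b in range(d):
            da = s[a] / m - mu0[a]
            db = s[b] / m - mu0[b]
            Lam[a, b] = Lambda0[a, b] + SS[a, b] - s[a] * s[b] / m + coef * da * db
    return const_m[m] - 0.5 * (nu0 + m) * _logdet_chol(Lam)


@njit(cache=True)
def _const_table(n, d, kappa0, nu0, logdet_L0):
    """const_m[m] collects every term of the cluster marginal likelihood
    that depends only on the cluster size m."""
    logpi = math.log(math.pi)
    mvlg0 = _mvlgamma(0.5 * nu0, d)
    out = np.empty(n + 2)
    for m in range(n + 2):
        out[m] = (
            -0.5 * m * d * logpi
            + _mvlgamma(0.5 * (nu0 + m), d)
            - mvlg0
            + 0.5 * d * (math.log(kappa0) - math.log(kappa0 + m))
            + 0.5 * nu0 * logdet_L0
        )
    return out


@njit(cache=True)
def run_chain(X, alpha, mu0, kappa0, nu0, Lambda0, n_iter, seed, z_init):
    """Run ``n_iter`` full Gibbs scans; returns an (n_iter, n) array of
    0-based allocation vectors, one per scan (not canonicalized)."""
    n, d = X.shape
    np.random.seed(seed)
    logdet_L0 = _logdet_chol(Lambda0)
    const_m = _const_table(n, d, kappa0, nu0, logdet_L0)

    counts = np.zeros(n + 1, np.int64)
    sums = np.zeros((n + 1, d))
    sqs = np.zeros((n + 1, d, d))
    clogml = np.zeros(n + 1)
    z = z_init.copy()
    k = int(z.max()) + 1
    for i in range(n):
        c = z[i]
        counts[c] += 1
        for a in range(d):
            sums[c, a] += X[i, a]
            for b in range(d):
                sqs[c, a, b] += X[i, a] * X[i, b]
    for c in range(k):
        clogml[c] = _logml(counts[c], sums[c], sqs[c], mu0, kappa0, Lambda0, nu0, const_m, d)

    draws = np.empty((n_iter, n), np.int32)
    logp = np.empty(n + 1)
    s_new = np.empty(d)
    SS_new = np.empty((d, d))
    log_alpha = math.log(alpha)

    for it in range(n_iter):
        for i in range(n):
            c = z[i]
            counts[c] -= 1
            for a in range(d):
                sums[c, a] -= X[i, a]
                for b in range(d):
                    sqs[c, a, b] -= X[i, a] * X[i, b]
            if counts[c] == 0:
                k -= 1
                if c != k:  # compact: move last cluster into the freed slot
                    counts[c] = counts[k]
                    for a in range(d):
                        sums[c, a] = sums[k, a]
                        for b in range(d):
                            sqs[c, a, b] = sqs[k, a, b]
                    clogml[c] = clogml[k]
                    for t in range(n):
                        if z[t] == k:
                            z[t] = c
                counts[k] = 0
                for a in range(d):
                    sums[k, a] = 0.0
                    for b in range(d):
                        sqs[k, a, b] = 0.0
                clogml[k] = 0.0
            else:
                clogml[c] = _logml(
                    counts[c], sums[c], sqs[c], mu0, kappa0, Lambda0, nu0, const_m, d
                )

            # allocation weights: existing clusters then a new one
            for c2 in range(k):
                for a in range(d):
                    s_new[a] = sums[c2, a] + X[i, a]
                    for b in range(d):
                        SS_new[a, b] = sqs[c2, a, b] + X[i, a] * X[i, b]
                lp = _logml(
                    counts[c2] + 1, s_new, SS_new, mu0, kappa0, Lambda0, nu0, const_m, d
                )
                logp[c2] = math.log(counts[c2]) + lp - clogml[c2]
            for a in range(d):
                s_new[a] = X[i, a]
                for b in range(d):
                    SS_new[a, b] = X[i, a] * X[i, b]
            logp[k] = log_alpha + _logml(
                1, s_new, SS_new, mu0, kappa0, Lambda0, nu0, const_m, d
            )

            mx = logp[0]
            for c2 in range(1, k + 1):
                if logp[c2] > mx:
                    mx = logp[c2]
            tot = 0.0
            for c2 in range(k + 1):
                logp[c2] = math.exp(logp[c2] - mx)
                tot += logp[c2]
            u = np.random.random() * tot
            cnew = k
            acc = 0.0
            for c2 in range(k + 1):
                acc += logp[c2]
                if u < acc:
                    cnew = c2
                    break
            z[i] = cnew
            if cnew == k:
                k += 1
            counts[cnew] += 1
            for a in range(d):
                sums[cnew, a] += X[i, a]
                for b in range(d):
                    sqs[cnew, a, b] += X[i, a] * X[i, b]
            clogml[cnew] = _logml(
                counts[cnew], sums[cnew], sqs[cnew], mu0, kappa0, Lambda0, nu0, const_m, d
            )
        for i in range(n):
            draws[it, i] = z[i]
    return draws


@njit(cache=True)
def binder_scores(cands, Q, const):
    """Posterior-expected Binder loss for each candidate row.

    ``Q = 1 - 2 * psm``; ``const = sum_{i<j} psm_ij``.  Score is
    ``const + sum_{i<j, co-clustered} Q_ij``.
    """
    M, n = cands.shape
    out = np.empty(M)
    for m in range(M):
        acc = 0.0
        for i in range(n):
            li = cands[m, i]
            for j in range(i + 1, n):
                if cands[m, j] == li:
                    acc += Q[i, j]
        out[m] = const + acc
    return out


@njit(cache=True)
def vilb_scores(cands, P, logr):
    """PSM lower bound of the posterior-expected VI for each candidate row.

    ``logr[i] = log sum_j p_ij`` (candidate-independent).  Score is
    ``(1/n) sum_i [log m_{z_i} + logr_i - 2 log sum_{j: z_j = z_i} p_ij]``.
    """
    M, n = cands.shape
    out = np.empty(M)
    sizes = np.zeros(n + 1, np.int64)
    for m in range(M):
        for c in range(n + 1):
            sizes[c] = 0
        for i in range(n):
            sizes[cands[m, i]] += 1
        acc = 0.0
        for i in range(n):
            li = cands[m, i]
            q = 0.0
            for j in range(n):
                if cands[m, j] == li:
                    q += P[i, j]
            acc += math.log(sizes[li]) + logr[i] - 2.0 * math.log(q)
        out[m] = acc / n
    return out


@njit(cache=True)
def psm_accumulate(draws, out):
    """Add each draw's co-clustering indicator matrix into ``out``."""
    M, n = draws.shape
    for m in range(M):
        for i in range(n):
            li = draws[m, i]
            out[i, i] += 1.0
            for j in range(i + 1, n):
                if draws[m, j] == li:
                    out[i, j] += 1.0
                    out[j, i] += 1.0


@njit(cache=True)
def canonicalize_rows(draws):
    """Order-of-appearance relabelling of each row, 1-based output."""
    M, n = draws.shape
    out = np.empty((M, n), np.int64)
    mapping = np.empty(n + 2, np.int64)
    for r in range(M):
        mapping[:] = 0
        nxt = 1
        for i in range(n):
            lab = draws[r, i]
            if mapping[lab] == 0:
                mapping[lab] = nxt
                nxt += 1
            out[r, i] = mapping[lab]
    return out
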