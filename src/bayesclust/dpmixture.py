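"""Dirichlet-process location-scale mixture of Gaussians.

The model places a DP prior (concentration ``alpha``) on the mixing measure
of a Gaussian kernel with conjugate normal-inverse-gamma base measure
(normal-inverse-Wishart for multivariate data):

    mu_j | Sigma_j ~ N(mu0, Sigma_j / c),    Sigma_j ~ IW(nu, Lambda0),

which for d = 1 reduces to ``sigma_j^2 ~ IG(nu/2, delta2/2)``.  Marginalizing
the weights yields the DP partition prior (see :func:`bayesclust.partition.
dp_eppf_log`), and conjugacy gives the cluster marginal likelihoods in
closed form, so the partition posterior

    pi(z | y)  ∝  eppf(z; alpha) * prod_j m(y_j)

can be evaluated exactly up to its normalizing constant and sampled with a
collapsed Gibbs scan over allocations.

Hyperparameters default to a data-dependent empirical recipe: ``mu0`` the
empirical mean, ``nu = d + 2`` (the smallest integer degrees of freedom
giving the marginal t prior on the cluster means a finite variance),
``delta2`` the empirical variance divided by the squared prior guess of the
number of clusters, and ``c = 0.01`` so that the between-cluster variance
exceeds the within-cluster variance a priori.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, multigammaln
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted

from . import _gibbs
from .partition import Partition, canonicalize, dp_eppf_log
from .samples import PartitionSamples

__all__ = [
    "NIGPrior",
    "MCMCConfig",
    "default_hyperparams",
    "log_marginal_likelihood",
    "log_posterior_partition",
    "alpha_schedule",
    "run_mcmc",
    "DPGaussianMixture",
]


@dataclass(frozen=True)
class NIGPrior:
    """Conjugate base measure: normal-inverse-gamma (d=1) / -Wishart (d>1).

    Attributes
    ----------
    mu0 : ndarray, shape (d,)
        Prior location of the cluster means.
    c : float
        Precision scale of the prior on the mean: ``mu | Sigma ~ N(mu0, Sigma/c)``.
    nu : float
        Degrees of freedom of the inverse-gamma / inverse-Wishart scale prior;
        requires ``nu > d - 1``.
    delta2 : ndarray, shape (d, d)
        Scale matrix (``[[delta^2]]`` when d = 1).
    """

    mu0: np.ndarray
    c: float
    nu: float
    delta2: np.ndarray = field(repr=False)

    def __init__(self, mu0, c, nu, delta2):
        mu0 = np.atleast_1d(np.asarray(mu0, dtype=np.float64))
        d = mu0.size
        delta2 = np.asarray(delta2, dtype=np.float64)
        if delta2.ndim == 0:
            delta2 = delta2.reshape(1, 1) if d == 1 else delta2 * np.eye(d)
        elif delta2.ndim == 1:
            delta2 = np.diag(delta2)
        if c <= 0:
            raise ValueError(f"c must be positive, got {c}")
        if nu <= max(0.0, d - 1):
            raise ValueError(f"nu must exceed d - 1 = {d - 1}, got {nu}")
        if delta2.shape != (d, d) or not np.allclose(delta2, delta2.T):
            raise ValueError("delta2 must be a symmetric d x d scale matrix")
        if np.linalg.eigvalsh(delta2)[0] <= 0:
            raise ValueError("delta2 must be positive definite")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "c", float(c))
        object.__setattr__(self, "nu", float(nu))
        object.__setattr__(self, "delta2", delta2)

    @property
    def d(self) -> int:
        return self.mu0.size


@dataclass(frozen=True)
class MCMCConfig:
    """Length, burn-in, thinning and seed of a Gibbs run.

    ``(iterations - burn_in) // thinning`` draws are retained.
    """

    iterations: int = 10_000
    burn_in: int = 1_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


def default_hyperparams(data: np.ndarray, k_hat: int = 2) -> NIGPrior:
    """Empirical-Bayes base-measure hyperparameters.

    ``mu0`` = empirical mean, ``c`` = 0.01, ``nu`` = d + 2, and ``delta2`` =
    empirical variance / ``k_hat**2`` (diagonal of the empirical covariance
    for d > 1), where ``k_hat`` is a prior guess of the number of clusters.
    The empirical variance upper-bounds the within-cluster variance, and
    dividing by ``k_hat^2`` concentrates the scale prior below it.
    """
    X = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n, d = X.shape
    if n < 2:
        raise ValueError("need n >= 2 observations to set empirical hyperparameters")
    if k_hat < 1:
        raise ValueError("k_hat must be >= 1")
    var = X.var(axis=0, ddof=1)
    return NIGPrior(mu0=X.mean(axis=0), c=0.01, nu=d + 2, delta2=np.diag(var) / k_hat**2)


def log_marginal_likelihood(cluster_data: np.ndarray, prior: NIGPrior) -> float:
    """Closed-form log marginal likelihood of one cluster.

    ``log ∫ prod_i N(y_i | mu, Sigma) dNIW(mu, Sigma)``; the empty cluster
    returns 0 (the empty product).  The one-observation case is the
    multivariate Student-t predictive implied by the base measure.
    """
    Y = np.asarray(cluster_data, dtype=np.float64)
    if Y.size == 0:
        return 0.0
    Y = np.atleast_2d(Y.reshape(-1, prior.d))
    m, d = Y.shape
    ybar = Y.mean(axis=0)
    dev = Y - ybar
    diff = ybar - prior.mu0
    lam_m = prior.delta2 + dev.T @ dev + (prior.c * m / (prior.c + m)) * np.outer(diff, diff)
    nu_m = prior.nu + m
    sign0, logdet0 = np.linalg.slogdet(prior.delta2)
    signm, logdetm = np.linalg.slogdet(lam_m)
    return float(
        -0.5 * m * d * math.log(math.pi)
        + multigammaln(0.5 * nu_m, d)
        - multigammaln(0.5 * prior.nu, d)
        + 0.5 * prior.nu * logdet0
        - 0.5 * nu_m * logdetm
        + 0.5 * d * (math.log(prior.c) - math.log(prior.c + m))
    )


def _cluster_logml_sum(X: np.ndarray, labels0: np.ndarray, k: int, prior: NIGPrior) -> float:
    """Sum of cluster log marginal likelihoods, vectorized over clusters."""
    n, d = X.shape
    counts = np.bincount(labels0, minlength=k).astype(np.float64)
    sums = np.zeros((k, d))
    np.add.at(sums, labels0, X)
    outers = X[:, :, None] * X[:, None, :]
    sqs = np.zeros((k, d, d))
    np.add.at(sqs, labels0, outers)
    m = counts[:, None, None]
    ybar = sums / counts[:, None]
    diff = ybar - prior.mu0
    lam = (
        prior.delta2
        + sqs
        - sums[:, :, None] * sums[:, None, :] / m
        + (prior.c * counts / (prior.c + counts))[:, None, None]
        * (diff[:, :, None] * diff[:, None, :])
    )
    nu_m = prior.nu + counts
    _, logdetm = np.linalg.slogdet(lam)
    _, logdet0 = np.linalg.slogdet(prior.delta2)
    terms = (
        -0.5 * counts * d * math.log(math.pi)
        + multigammaln(0.5 * nu_m, d)
        - multigammaln(0.5 * prior.nu, d)
        + 0.5 * prior.nu * logdet0
        - 0.5 * nu_m * logdetm
        + 0.5 * d * (np.log(prior.c) - np.log(prior.c + counts))
    )
    return float(terms.sum())


def log_posterior_partition(
    z: Partition | np.ndarray, data: np.ndarray, prior: NIGPrior, alpha: float
) -> float:
    """Unnormalized log posterior of a partition under the DP mixture.

    ``dp_eppf_log(z, alpha) + sum_j log m(y_j)``.  Depends on ``z`` only
    through the underlying set partition.
    """
    z = canonicalize(z)
    X = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if X.shape[0] != z.n:
        raise ValueError(f"partition length {z.n} does not match n = {X.shape[0]}")
    return dp_eppf_log(z, alpha) + _cluster_logml_sum(X, z.labels - 1, z.k, prior)


def alpha_schedule(rule, n: int | None = None) -> float:
    """Resolve a DP concentration: a fixed positive value or ``"1/log(n)"``.

    The sample-size dependent rule uses the natural logarithm and requires
    ``n >= 2``.
    """
    if isinstance(rule, str):
        if rule.replace(" ", "") not in {"1/log(n)", "1/logn", "logn"}:
            raise ValueError(f"unknown alpha rule {rule!r}")
        if n is None or n <= 1:
            raise ValueError("the 1/log(n) rule requires n >= 2")
        return 1.0 / math.log(n)
    alpha = float(rule)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha


def run_mcmc(
    data: np.ndarray,
    prior: NIGPrior,
    alpha: float,
    config: MCMCConfig,
) -> PartitionSamples:
    """Collapsed Gibbs sampling of the DP Gaussian mixture partition posterior.

    Runs ``config.iterations`` full scans from a single-cluster start,
    discards ``config.burn_in`` and keeps every ``config.thinning``-th scan.
    The chain's stationary distribution is proportional to
    ``exp(log_posterior_partition)``.  Identical inputs give identical draws.
    """
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(data, dtype=np.float64)))
    n, d = X.shape
    if n == 0:
        raise ValueError("empty dataset")
    if d != prior.d:
        raise ValueError(f"data dimension {d} does not match prior dimension {prior.d}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    z0 = np.zeros(n, dtype=np.int64)
    raw = _gibbs.run_chain(
        X,
        float(alpha),
        np.ascontiguousarray(prior.mu0),
        float(prior.c),
        float(prior.nu),
        np.ascontiguousarray(prior.delta2),
        int(config.iterations),
        int(config.seed) % 2**31,
        z0,
    )
    kept = raw[config.burn_in + config.thinning - 1 :: config.thinning]
    meta = {
        "sampler": "collapsed-gibbs",
        "alpha": float(alpha),
        "seed": int(config.seed),
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "thinning": config.thinning,
        "prior": {
            "mu0": prior.mu0.tolist(),
            "c": prior.c,
            "nu": prior.nu,
            "delta2": prior.delta2.tolist(),
        },
    }
    return PartitionSamples(kept.astype(np.int64), meta=meta)


class DPGaussianMixture(ClusterMixin, BaseEstimator):
    """Bayesian clustering with a DP mixture of Gaussians.

    Fitting runs collapsed Gibbs sampling of the partition posterior and
    summarizes it with a decision-theoretic point estimate.  Posterior draws,
    the posterior similarity matrix and the point estimate are exposed as
    fitted attributes; further summaries (other losses, credible balls) can
    be computed from ``samples_`` with :mod:`bayesclust.summaries`.

    Parameters
    ----------
    alpha : float or "1/log(n)", default=1.0
        DP concentration, or the sample-size dependent rule.
    k_hat : int, default=2
        Prior guess of the number of clusters, used by the empirical
        hyperparameter recipe (ignored when ``prior`` is given).
    prior : NIGPrior, optional
        Explicit base measure; overrides the empirical recipe.
    loss : {"vi", "binder", "zero-one"}, default="vi"
        Loss minimized for the reported point estimate ``labels_``.
    iterations, burn_in, thinning : int
        MCMC schedule.
    random_state : int or RandomState, optional
        Seed for the sampler.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        0-based cluster labels of the point-estimate partition.
    n_clusters_ : int
        Its number of clusters.
    estimate_ : EstimatorResult
        Point estimate with loss name and objective value.
    samples_ : PartitionSamples
        Posterior partition draws.
    psm_ : ndarray of shape (n, n)
        Posterior similarity matrix.
    prior_ : NIGPrior
        Base measure actually used.
    alpha_ : float
        Concentration actually used.

    Examples
    --------
    >>> from bayesclust.datasets import gen_gaussian_mixture, MixtureSpec
    >>> spec = MixtureSpec([0.5, 0.5], [[-5.0], [5.0]], [1.0, 1.0])
    >>> X, truth = gen_gaussian_mixture(100, spec, seed=0)
    >>> model = DPGaussianMixture(alpha=1.0, iterations=500, burn_in=100,
    ...                           random_state=0).fit(X)
    >>> model.n_clusters_
    2
    """

    def __init__(
        self,
        alpha=1.0,
        k_hat: int = 2,
        prior: NIGPrior | None = None,
        loss: str = "vi",
        iterations: int = 10_000,
        burn_in: int = 1_000,
        thinning: int = 1,
        random_state=None,
    ):
        self.alpha = alpha
        self.k_hat = k_hat
        self.prior = prior
        self.loss = loss
        self.iterations = iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.random_state = random_state

    def fit(self, X, y=None):
        from . import summaries  # deferred: summaries imports this module

        X = check_array(X, ensure_min_samples=2)
        n = X.shape[0]
        self.prior_ = self.prior if self.prior is not None else default_hyperparams(X, self.k_hat)
        self.alpha_ = alpha_schedule(self.alpha, n)
        if isinstance(self.random_state, (int, np.integer)):
            seed = int(self.random_state)
        else:
            seed = int(check_random_state(self.random_state).randint(2**31 - 1))
        config = MCMCConfig(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=seed,
        )
        self.samples_ = run_mcmc(X, self.prior_, self.alpha_, config)
        self.psm_ = summaries.posterior_similarity(self.samples_)
        self.estimate_ = summaries.estimate(
            self.samples_,
            self.loss,
            psm=self.psm_,
            data=X,
            prior=self.prior_,
            alpha=self.alpha_,
        )
        self.labels_ = self.estimate_.partition.labels - 1
        self.n_clusters_ = self.estimate_.k
        self._X_fit = X
        return self

    def point_estimate(self, loss: str = "vi", **kwargs):
        """Point-estimate partition under another loss, from the stored draws."""
        from . import summaries

        check_is_fitted(self, "samples_")
        return summaries.estimate(
            self.samples_,
            loss,
            psm=self.psm_,
            data=self._X_fit,
            prior=self.prior_,
            alpha=self.alpha_,
            **kwargs,
        )

    def credible_ball(self, metric: str = "vi", level: float = 0.95):
        """Credible ball of posterior draws around the fitted point estimate."""
        from . import summaries

        check_is_fitted(self, "estimate_")
        return summaries.credible_ball(
            self.samples_, self.estimate_.partition, metric=metric, level=level
        )
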