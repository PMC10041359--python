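import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import bayesclust as bc
from bayesclust.dpmixture import (
    MCMCConfig,
    NIGPrior,
    alpha_schedule,
    default_hyperparams,
    log_marginal_likelihood,
    log_posterior_partition,
    run_mcmc,
)

from conftest import enumerated_posterior, set_partitions


class TestDefaultHyperparams:
    def test_univariate_recipe(self, rng):
        X = rng.normal(size=(50, 1)) * 2.0
        prior = default_hyperparams(X, k_hat=2)
        assert prior.nu == 3  # d + 2
        assert prior.c == 0.01
        assert prior.mu0 == pytest.approx(X.mean())
        assert prior.delta2[0, 0] == pytest.approx(X.var(ddof=1) / 4)

    def test_variance_four_khat_two_gives_one(self):
        X = np.array([[-2.0], [0.0], [2.0], [0.0], [-2.0], [2.0], [0.0]])
        X = X * math.sqrt(4.0 / X.var(ddof=1))
        prior = default_hyperparams(X, k_hat=2)
        assert prior.delta2[0, 0] == pytest.approx(1.0)

    def test_multivariate_recipe(self, rng):
        X = rng.normal(size=(40, 2)) * [1.0, 3.0]
        prior = default_hyperparams(X, k_hat=3)
        assert prior.nu == 4  # d + 2
        assert np.allclose(np.diag(prior.delta2), X.var(axis=0, ddof=1) / 9)
        assert prior.delta2[0, 1] == 0.0

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            default_hyperparams(np.array([[1.0]]), k_hat=2)


class TestNIGPrior:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu0=[0.0], c=-1.0, nu=3.0, delta2=1.0),
            dict(mu0=[0.0], c=0.5, nu=0.0, delta2=1.0),
            dict(mu0=[0.0, 0.0], c=0.5, nu=0.5, delta2=np.eye(2)),  # nu <= d-1
            dict(mu0=[0.0], c=0.5, nu=3.0, delta2=-2.0),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            NIGPrior(**kwargs)


class TestLogMarginalLikelihood:
    prior = NIGPrior(mu0=[0.3], c=0.5, nu=3.0, delta2=2.0)

    def test_empty_cluster_is_log_one(self):
        assert log_marginal_likelihood(np.empty((0, 1)), self.prior) == 0.0

    def test_single_point_is_student_t_predictive(self):
        # marginal t with df nu, location mu0, scale^2 = delta2 (1 + 1/c) / nu
        for y in (-1.3, 0.0, 2.4):
            scale = math.sqrt(2.0 * (1 + 1 / 0.5) / 3.0)
            expected = stats.t.logpdf(y, df=3.0, loc=0.3, scale=scale)
            assert log_marginal_likelihood([[y]], self.prior) == pytest.approx(
                expected, abs=1e-10
            )

    def test_single_point_matches_quadrature(self):
        # integrate the scale numerically; the location integral
        # N(y|mu, s2) * N(mu|mu0, s2/c) d mu = N(y|mu0, s2 (1 + 1/c)) is exact
        y = 1.7

        def integrand(s2):
            return stats.norm.pdf(y, 0.3, math.sqrt(s2 * (1 + 1 / 0.5))) * (
                stats.invgamma.pdf(s2, 1.5, scale=1.0)
            )

        from scipy.integrate import quad

        val, _ = quad(integrand, 0, np.inf)
        assert log_marginal_likelihood([[y]], self.prior) == pytest.approx(
            math.log(val), abs=1e-6
        )

    def test_sequential_decomposition(self, rng):
        # m(y1, y2) = m(y1) * predictive(y2 | y1), with the predictive computed
        # as a ratio of marginals on an augmented one-point "cluster prior"
        y1, y2 = rng.normal(size=2)
        joint = log_marginal_likelihood([[y1], [y2]], self.prior)
        first = log_marginal_likelihood([[y1]], self.prior)
        # posterior after y1 is again normal-inverse-gamma; form it explicitly
        c1 = self.prior.c + 1
        mu1 = (self.prior.c * 0.3 + y1) / c1
        nu1 = self.prior.nu + 1
        d21 = 2.0 + (self.prior.c / c1) * (y1 - 0.3) ** 2
        post = NIGPrior(mu0=[mu1], c=c1, nu=nu1, delta2=d21)
        pred = log_marginal_likelihood([[y2]], post)
        assert joint == pytest.approx(first + pred, abs=1e-10)

    def test_multivariate_single_point_is_multivariate_t(self, rng):
        # one observation in d = 2: the marginal is the multivariate Student-t
        # predictive with df nu - d + 1 and shape delta2 (c + 1) / (c (nu - d + 1))
        prior2 = NIGPrior(
            mu0=[0.5, -0.5], c=0.2, nu=4.0,
            delta2=np.array([[1.0, 0.3], [0.3, 2.0]]),
        )
        y = rng.normal(size=(1, 2))
        df = 4.0 - 2 + 1
        shape = prior2.delta2 * (0.2 + 1) / (0.2 * df)
        expected = stats.multivariate_t.logpdf(y[0], loc=prior2.mu0, shape=shape, df=df)
        assert log_marginal_likelihood(y, prior2) == pytest.approx(expected, abs=1e-10)


class TestLogPosteriorPartition:
    def test_relabel_invariance(self, rng):
        X = rng.normal(size=(6, 1))
        prior = default_hyperparams(X, 2)
        z = np.array([1, 2, 1, 3, 2, 1])
        relab = np.array([5, 9, 5, 2, 9, 5])
        assert log_posterior_partition(z, X, prior, 1.0) == pytest.approx(
            log_posterior_partition(relab, X, prior, 1.0), abs=1e-10
        )

    def test_normalized_enumeration_sums_to_one(self, rng):
        X = rng.normal(size=(5, 1))
        prior = default_hyperparams(X, 2)
        parts, probs = enumerated_posterior(X, prior, 1.0, log_posterior_partition)
        assert len(parts) == 52
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_far_outlier_prefers_own_cluster(self):
        # tight cluster at 0 plus an outlier at 12: with a small prior scale,
        # the singleton split beats absorbing the outlier
        X = np.array([[-0.1], [0.0], [0.1], [0.05], [12.0]])
        prior = NIGPrior(mu0=[X.mean()], c=0.01, nu=3.0, delta2=0.05)
        together = log_posterior_partition([1, 1, 1, 1, 1], X, prior, 1.0)
        split = log_posterior_partition([1, 1, 1, 1, 2], X, prior, 1.0)
        assert split > together

    def test_length_mismatch(self, rng):
        X = rng.normal(size=(4, 1))
        prior = default_hyperparams(X, 2)
        with pytest.raises(ValueError):
            log_posterior_partition([1, 1, 2], X, prior, 1.0)


class TestAlphaSchedule:
    def test_logn_rule(self):
        assert alpha_schedule("1/log(n)", 100) == pytest.approx(1 / math.log(100))

    def test_fixed_passthrough(self):
        assert alpha_schedule(0.5) == 0.5

    def test_logn_requires_n_at_least_two(self):
        with pytest.raises(ValueError):
            alpha_schedule("1/log(n)", 1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            alpha_schedule(-1.0)
        with pytest.raises(ValueError):
            alpha_schedule("harmonic", 10)


class TestMCMCConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=10, burn_in=10)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=10, burn_in=2, thinning=0)

    def test_kept_count(self):
        assert MCMCConfig(iterations=100, burn_in=10, thinning=3).n_kept == 30


class TestRunMCMC:
    def test_bookkeeping_and_determinism(self, rng):
        X = rng.normal(size=(8, 1))
        prior = default_hyperparams(X, 2)
        cfg = MCMCConfig(iterations=200, burn_in=50, thinning=3, seed=4)
        s1 = run_mcmc(X, prior, 1.0, cfg)
        s2 = run_mcmc(X, prior, 1.0, cfg)
        assert s1.n_draws == (200 - 50) // 3
        assert np.array_equal(s1.draws, s2.draws)
        s3 = run_mcmc(X, prior, 1.0, MCMCConfig(200, 50, 3, seed=5))
        assert not np.array_equal(s1.draws, s3.draws)

    def test_chain_matches_enumerated_posterior(self, rng):
        X = rng.normal(size=(5, 1))
        prior = default_hyperparams(X, 2)
        parts, probs = enumerated_posterior(X, prior, 1.0, log_posterior_partition)
        index = {tuple((np.asarray(p) - 1).tolist()): i for i, p in enumerate(parts)}
        samples = run_mcmc(X, prior, 1.0, MCMCConfig(42_000, 2_000, seed=42))
        emp = np.zeros(len(parts))
        for key, c in Counter(map(tuple, (samples.draws - 1).tolist())).items():
            emp[index[key]] += c
        emp /= emp.sum()
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.02

    def test_gibbs_scan_leaves_posterior_invariant(self, rng):
        # exact transition-matrix check of the full-conditional math on n = 4
        X = rng.normal(size=(4, 1))
        prior = default_hyperparams(X, 2)
        alpha = 0.8
        parts, probs = enumerated_posterior(X, prior, alpha, log_posterior_partition)
        states = [tuple((np.asarray(p) - 1).tolist()) for p in parts]
        index = {s: i for i, s in enumerate(states)}
        n, S = 4, len(states)
        pi = probs.copy()
        for site in range(n):
            T = np.zeros((S, S))
            for s_idx, state in enumerate(states):
                weights, targets = [], []
                others = sorted(set(state) - {state[site]}) + [max(state) + 1]
                seen = set()
                for cand in set(state) | {max(state) + 1}:
                    trial = list(state)
                    trial[site] = cand
                    canon = tuple(
                        (bc.canonicalize(np.asarray(trial) + 1).labels - 1).tolist()
                    )
                    if canon in seen:
                        continue
                    seen.add(canon)
                    lp = log_posterior_partition(
                        np.asarray(canon) + 1, X, prior, alpha
                    )
                    weights.append(lp)
                    targets.append(index[canon])
                w = np.exp(np.asarray(weights) - max(weights))
                w /= w.sum()
                for t_idx, wt in zip(targets, w):
                    T[s_idx, t_idx] += wt
            pi = pi @ T
        assert np.allclose(pi, probs, atol=1e-10)

    def test_empty_data_rejected(self):
        prior = NIGPrior(mu0=[0.0], c=0.5, nu=3.0, delta2=1.0)
        with pytest.raises(ValueError):
            run_mcmc(np.empty((0, 1)), prior, 1.0, MCMCConfig(10, 1))


class TestDPGaussianMixtureEstimator:
    def test_fit_recovers_well_separated_components(self):
        spec = bc.MixtureSpec([0.5, 0.5], [[-6.0], [6.0]], [1.0, 1.0])
        X, truth = bc.gen_gaussian_mixture(80, spec, seed=0)
        model = bc.DPGaussianMixture(
            alpha=1.0, iterations=800, burn_in=200, random_state=0
        ).fit(X)
        assert model.n_clusters_ == 2
        assert bc.Partition(model.labels_ + 1) == truth
        assert model.psm_.shape == (80, 80)
        assert model.samples_.n_draws == 600

    def test_alpha_rule_resolution(self):
        X = bc.gen_standard_normal(60, seed=2)
        model = bc.DPGaussianMixture(
            alpha="1/log(n)", iterations=300, burn_in=100, random_state=1
        ).fit(X)
        assert model.alpha_ == pytest.approx(1 / math.log(60))

    def test_point_estimate_other_losses(self):
        X = bc.gen_standard_normal(40, seed=3)
        model = bc.DPGaussianMixture(
            alpha=0.5, iterations=400, burn_in=100, random_state=2
        ).fit(X)
        for loss in ("vi", "binder", "zero-one"):
            res = model.point_estimate(loss)
            assert res.partition.n == 40
        ball = model.credible_ball(level=0.9)
        assert ball.radius >= 0.0
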