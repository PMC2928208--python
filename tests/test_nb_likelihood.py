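"""Negative-binomial pmf and Monte-Carlo marginal likelihood."""

import math

import numpy as np
import pytest
from scipy import stats

from ebcount import (
    CountData,
    ModelDefinition,
    NBParams,
    PriorSample,
    marginal_likelihood,
    marginal_log_likelihoods,
    nb_log_pmf,
)


def nb_pmf_recurrence(u_max, l, mu, phi):
    """Oracle: pmf via the product-form recurrence
    P(u)/P(u-1) = (u-1+1/phi)/u * m/(m+1/phi), seeded at the closed form
    P(0) = (1+m*phi)^(-1/phi)."""
    m, r = l * mu, 1.0 / phi
    p = [(1.0 + m * phi) ** (-r)]
    for u in range(1, u_max + 1):
        p.append(p[-1] * (u - 1 + r) / u * m / (m + r))
    return np.array(p)


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        # pmf at u=0 is (1/(1+l*mu*phi))^(1/phi) = 1/2 here
        assert nb_log_pmf(0, 1.0, NBParams(mu=1.0, phi=1.0)) == pytest.approx(
            math.log(0.5)
        )

    def test_geometric_special_case(self):
        # phi=1, l*mu=1 reduces to Geometric(1/2): P(3) = 2^-4
        assert nb_log_pmf(3, 1.0, NBParams(mu=1.0, phi=1.0)) == pytest.approx(
            math.log(2.0**-4)
        )

    def test_matches_recurrence_oracle(self):
        l, mu, phi = 2.0, 1.3, 0.4
        oracle = nb_pmf_recurrence(5, l, mu, phi)
        got = nb_log_pmf(np.arange(6), l, mu=mu, phi=phi)
        np.testing.assert_allclose(np.exp(got), oracle, rtol=1e-12)

    def test_matches_scipy_nbinom(self):
        # independent cross-check against scipy's parametrization
        l, mu, phi = 500.0, 0.01, 0.7
        r = 1 / phi
        p = r / (r + l * mu)
        u = np.arange(30)
        np.testing.assert_allclose(
            nb_log_pmf(u, l, mu=mu, phi=phi),
            stats.nbinom.logpmf(u, r, p),
            rtol=1e-10,
        )

    @pytest.mark.parametrize(
        "l, mu, phi",
        [(1.0, 2.0, 0.5), (50.0, 0.1, 1.3), (3.0, 0.7, 0.0), (10.0, 1.0, 2.0)],
    )
    def test_pmf_sums_to_one(self, l, mu, phi):
        # adaptive truncation: extend until the tail bound is negligible
        m = l * mu
        sd = math.sqrt(m * (1 + m * phi))
        hi = int(m + 40 * sd + 200)
        total = np.exp(nb_log_pmf(np.arange(hi), l, mu=mu, phi=phi)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        # the exact NB-Poisson log-pmf gap has leading term phi*u*(u-1)/2,
        # so convergence is checked against that analytic envelope
        u = np.arange(51)
        l, mu, phi = 3.0, 1.7, 1e-8
        near = nb_log_pmf(u, l, mu=mu, phi=phi)
        exact = stats.poisson.logpmf(u, l * mu)
        gap = np.abs(near - exact)
        envelope = phi * (u * (u - 1) / 2 + u * l * mu + (l * mu) ** 2) + 1e-7
        assert np.all(gap <= envelope)
        assert np.max(gap[u <= 14]) < 1e-6

    def test_phi_zero_is_exact_poisson(self):
        u = np.arange(20)
        np.testing.assert_allclose(
            nb_log_pmf(u, 2.0, mu=3.0, phi=0.0),
            stats.poisson.logpmf(u, 6.0),
            rtol=1e-12,
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, mu=1.0, phi=0.5)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 0.0, mu=1.0, phi=0.5)
        with pytest.raises(ValueError):
            NBParams(mu=0.0, phi=0.5)
        with pytest.raises(ValueError):
            NBParams(mu=1.0, phi=-0.1)


def make_prior(model, mus, phis):
    return PriorSample(model=model, mus=mus, phis=np.asarray(phis, dtype=float))


class TestMarginalLikelihood:
    def test_single_prior_pair_reduces_to_pmf_sum(self):
        model = ModelDefinition("de", [[0, 1], [2, 3]])
        prior = make_prior(model, [np.array([0.01]), np.array([0.03])], [0.4])
        u = [3, 5, 9, 12]
        l = [400.0, 500.0, 450.0, 520.0]
        expected = (
            nb_log_pmf(np.array(u[:2]), np.array(l[:2]), mu=0.01, phi=0.4).sum()
            + nb_log_pmf(np.array(u[2:]), np.array(l[2:]), mu=0.03, phi=0.4).sum()
        )
        assert marginal_likelihood(u, l, model, prior) == pytest.approx(expected)

    def test_all_zero_counts_closed_form(self, rng):
        model = ModelDefinition("all", [[0, 1, 2]])
        mus = rng.lognormal(-6, 1, 40)
        phis = rng.gamma(1.0, 0.5, 40)
        prior = make_prior(model, [mus], phis)
        l = np.array([100.0, 200.0, 150.0])
        # P(0...0 | theta) = prod_i (1 + l_i mu phi)^(-1/phi)
        per_theta = np.prod(
            (1 + l[None, :] * mus[:, None] * phis[:, None]) ** (-1 / phis[:, None]),
            axis=1,
        )
        expected = math.log(per_theta.mean())
        assert marginal_likelihood([0, 0, 0], l, model, prior) == pytest.approx(expected)

    def test_matches_naive_double_loop(self, rng):
        # moderate magnitudes so the naive product form does not underflow
        model = ModelDefinition("one", [[0, 1]])
        mus = rng.choice(np.linspace(0.005, 0.05, 10), 50)
        phis = rng.choice(np.linspace(0.1, 1.0, 5), 50)
        prior = make_prior(model, [mus], phis)
        u, l = [4, 7], np.array([300.0, 350.0])
        naive = 0.0
        for mu, phi in zip(mus, phis):
            prod = 1.0
            for ui, li in zip(u, l):
                prod *= math.exp(nb_log_pmf(ui, li, mu=mu, phi=phi))
            naive += prod
        naive /= len(mus)
        assert marginal_likelihood(u, l, model, prior) == pytest.approx(
            math.log(naive), rel=1e-10
        )

    def test_invariance_under_permutations(self, rng):
        model = ModelDefinition("de", [[0, 1, 2], [3, 4]])
        T = 30
        mus = [rng.lognormal(-5, 1, T), rng.lognormal(-5, 1, T)]
        phis = rng.gamma(0.85, 0.5, T)
        prior = make_prior(model, mus, phis)
        u = np.array([3, 9, 5, 20, 14])
        l = np.array([300.0, 410.0, 290.0, 350.0, 380.0])
        base = marginal_likelihood(u, l, model, prior)

        # permute samples within the first set
        perm = [2, 0, 1, 3, 4]
        assert marginal_likelihood(u[perm], l[perm], model, prior) == pytest.approx(base)

        # permute the prior sample entries (jointly across sets)
        shuffle = rng.permutation(T)
        prior2 = make_prior(model, [m[shuffle] for m in mus], phis[shuffle])
        assert marginal_likelihood(u, l, model, prior2) == pytest.approx(base)

    def test_monte_carlo_convergence(self, rng):
        # relative error vs a dense quantile-grid quadrature shrinks with |Theta|
        model = ModelDefinition("all", [[0, 1, 2]])
        data = CountData(
            counts=np.array([[7, 11, 4]]),
            lib_sizes=np.array([40000.0, 60000.0, 50000.0]),
        )
        mu_d = stats.lognorm(s=0.5, scale=1e-4)
        phi_d = stats.gamma(2.0, scale=0.25)
        qs = (np.arange(800) + 0.5) / 800
        MU, PHI = np.meshgrid(mu_d.ppf(qs), phi_d.ppf(qs), indexing="ij")
        oracle = marginal_log_likelihoods(
            data, model, make_prior(model, [MU.ravel()], PHI.ravel())
        )[0]
        errs = []
        for T in (100, 10000):
            prior = make_prior(
                model,
                [mu_d.rvs(T, random_state=rng)],
                phi_d.rvs(T, random_state=rng),
            )
            mc = marginal_log_likelihoods(data, model, prior)[0]
            errs.append(abs(np.exp(mc - oracle) - 1.0))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_empty_prior_rejected(self):
        model = ModelDefinition("all", [[0, 1]])
        with pytest.raises(ValueError):
            PriorSample(model=model, mus=[np.array([])], phis=np.array([]))

    def test_prior_model_mismatch(self, toy_data):
        m1 = ModelDefinition("a", [[0, 1], [2, 3]])
        m2 = ModelDefinition("b", [[0, 1, 2, 3]])
        prior = make_prior(m1, [np.array([0.01]), np.array([0.01])], [0.1])
        with pytest.raises(ValueError, match="different model"):
            marginal_log_likelihoods(toy_data, m2, prior)
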