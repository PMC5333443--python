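import numpy as np
import pytest
from scipy import stats

from seqvpc import (CompoundPoissonMixedModel, CPFeatureParams, CPObsParams,
                    NBFeatureParams, NegativeBinomialMixedModel, cp_logpdf,
                    cp_sample, fit_glmm_feature, fit_null_feature,
                    marginal_loglik, make_design, simulate_feature)


def nb_sim_feature(alpha, phi, sigma2, S, R, rng):
    starts = np.arange(0, S * R + 1, R).astype(np.int64)
    y = simulate_feature(NBFeatureParams(alpha, phi, sigma2), starts, rng)
    return y, np.repeat(np.arange(S), R)


class TestMarginalLoglik:
    def test_sigma2_zero_equals_glm_sum(self, rng):
        y, groups = nb_sim_feature(2.0, 0.4, 0.5, 10, 3, rng)
        prm = NBFeatureParams(1.8, 0.3, 0.0)
        got = marginal_loglik(y, groups, prm, "NB")
        r = 1 / prm.phi
        mu = np.exp(prm.alpha)
        expected = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_nb_matches_trapezoid_oracle(self):
        # one strain, one observation: a single 1-D integral
        alpha, phi, s2 = 1.2, 0.4, 0.8
        y = np.array([7.0])
        b = np.linspace(-8 * np.sqrt(s2), 8 * np.sqrt(s2), 2001)
        r = 1 / phi
        mu = np.exp(alpha + b)
        integrand = np.exp(stats.nbinom.logpmf(7, r, r / (r + mu))
                           + stats.norm.logpdf(b, 0, np.sqrt(s2)))
        oracle = np.log(np.trapezoid(integrand, b))
        # needs 2 strains to build the model; use two copies and halve
        got = marginal_loglik(np.array([7.0, 7.0]), np.array(["a", "b"]),
                              NBFeatureParams(alpha, phi, s2), "NB", n_quad=61)
        assert got / 2 == pytest.approx(oracle, abs=1e-6)

    def test_cp_matches_trapezoid_oracle(self):
        alpha, phi, p, s2 = 1.2, 0.8, 1.5, 0.8
        yv = 3.3
        b = np.linspace(-8 * np.sqrt(s2), 8 * np.sqrt(s2), 2001)
        dens = np.array([cp_logpdf(yv, CPObsParams(np.exp(alpha + bi), phi, p))
                         for bi in b])
        integrand = np.exp(dens + stats.norm.logpdf(b, 0, np.sqrt(s2)))
        oracle = np.log(np.trapezoid(integrand, b))
        got = marginal_loglik(np.array([yv, yv]), np.array(["a", "b"]),
                              CPFeatureParams(alpha, phi, p, s2), "CP", n_quad=61)
        assert got / 2 == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_strain_and_replicate_permutations(self, rng):
        y, groups = nb_sim_feature(2.0, 0.4, 0.7, 8, 3, rng)
        prm = NBFeatureParams(2.0, 0.4, 0.7)
        base = marginal_loglik(y, groups, prm, "NB")
        perm = rng.permutation(len(y))
        assert marginal_loglik(y[perm], groups[perm], prm, "NB") == \
            pytest.approx(base, abs=1e-9)

    def test_quadrature_node_stability(self, rng):
        for _ in range(5):
            y, groups = nb_sim_feature(rng.uniform(1, 5), rng.uniform(0.1, 1),
                                       rng.uniform(0.1, 2), 12, 3, rng)
            prm = NBFeatureParams(2.0, 0.5, 1.0)
            a = marginal_loglik(y, groups, prm, "NB", n_quad=25)
            b = marginal_loglik(y, groups, prm, "NB", n_quad=61)
            assert abs(a - b) < 1e-4


class TestFitNB:
    def test_parameter_recovery(self, rng):
        # ~50 features at the larger-replicate design; acceptance runs 200
        s2s, phis = [], []
        for _ in range(50):
            y, groups = nb_sim_feature(3.0, 0.3, 1.0, 50, 6, rng)
            res = NegativeBinomialMixedModel(y, groups).fit()
            s2s.append(res.params.sigma2)
            phis.append(res.params.phi)
        assert abs(np.mean(s2s) - 1.0) < 0.1
        assert abs(np.mean(phis) - 0.3) < 0.1

    def test_boundary_pileup_under_null(self, rng):
        zeros = 0
        for _ in range(50):
            y, groups = nb_sim_feature(2.0, 0.5, 0.0, 30, 3, rng)
            res = NegativeBinomialMixedModel(y, groups).fit()
            zeros += res.params.sigma2 == 0.0
        # the boundary null piles ~half of the estimates at exactly 0
        assert zeros >= 20

    def test_alternative_dominates_null(self, rng):
        for _ in range(20):
            y, groups = nb_sim_feature(rng.uniform(1, 4), rng.uniform(0.05, 1.5),
                                       rng.uniform(0, 2), 20, 3, rng)
            alt = fit_glmm_feature(y, groups, "NB")
            null = fit_null_feature(y, groups, "NB")
            assert alt.llf >= null.llf - 1e-6

    def test_all_zero_feature_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            NegativeBinomialMixedModel(np.zeros(6), ["a", "a", "a", "b", "b", "b"])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            NegativeBinomialMixedModel([1.5, 2, 3, 4], ["a", "a", "b", "b"])


class TestFitNull:
    def test_nb_null_recovers_alpha_and_phi(self, rng):
        # the MLE of phi at n=300 has sd ~ 0.05, so judge recovery on the
        # average over replicate datasets
        mu, phi, n = np.exp(2.0), 0.5, 300
        r = 1 / phi
        alphas, phis = [], []
        for _ in range(10):
            y = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
            res = fit_null_feature(y, np.arange(n) % 2, "NB")
            alphas.append(res.params.alpha)
            phis.append(res.params.phi)
            assert res.params.sigma2 == 0.0
        se_alpha = np.sqrt((mu + phi * mu ** 2) / n) / mu
        assert abs(np.mean(alphas) - 2.0) < 3 * se_alpha / np.sqrt(10)
        assert abs(np.mean(phis) - phi) / phi < 0.10

    def test_null_loglik_equals_marginal_at_zero(self, rng):
        y, groups = nb_sim_feature(2.0, 0.4, 0.5, 10, 3, rng)
        res = fit_null_feature(y, groups, "NB")
        again = marginal_loglik(y, groups, res.params, "NB")
        assert res.llf == pytest.approx(again, abs=1e-9)

    def test_cp_null_recovers_power(self, rng):
        # the Tweedie power MLE has sd ~ 0.25 at n=300; judge the average
        ps = []
        for _ in range(10):
            y = cp_sample(300, CPObsParams(np.exp(2.0), 0.8, 1.5), rng)
            res = fit_null_feature(y, np.arange(300) % 2, "CP")
            ps.append(res.params.p)
        assert abs(np.mean(ps) - 1.5) < 0.1


class TestFitCP:
    def test_parameter_recovery(self, rng):
        s2s, ps = [], []
        starts = np.arange(0, 50 * 6 + 1, 6).astype(np.int64)
        groups = np.repeat(np.arange(50), 6)
        for _ in range(25):
            y = simulate_feature(CPFeatureParams(2.0, 0.8, 1.5, 1.0), starts, rng)
            res = CompoundPoissonMixedModel(y, groups).fit()
            s2s.append(res.params.sigma2)
            ps.append(res.params.p)
        assert abs(np.mean(s2s) - 1.0) < 0.15
        assert abs(np.mean(ps) - 1.5) < 0.05

    def test_alternative_dominates_null(self, rng):
        starts = np.arange(0, 20 * 3 + 1, 3).astype(np.int64)
        groups = np.repeat(np.arange(20), 3)
        for _ in range(10):
            y = simulate_feature(CPFeatureParams(1.5, 1.0, 1.4,
                                                 rng.uniform(0, 1.5)), starts, rng)
            alt = fit_glmm_feature(y, groups, "CP")
            null = fit_null_feature(y, groups, "CP")
            assert alt.llf >= null.llf - 1e-6

    def test_summary_mentions_vpc(self, rng):
        starts = np.arange(0, 22, 3).astype(np.int64)
        y = simulate_feature(CPFeatureParams(2.0, 0.8, 1.5, 0.5), starts, rng)
        res = CompoundPoissonMixedModel(y, np.repeat(np.arange(7), 3)).fit()
        s = res.summary()
        assert "VPC" in s and "sigma2" in s
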