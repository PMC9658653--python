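import numpy as np
import pytest
from scipy import integrate, stats

import oracles
from hpdsize import (
    BetaPrior,
    BSplinePrior,
    MultimodalDensityError,
    hpd_fixed_coverage,
    hpd_fixed_length,
    posterior,
    predictive_pmf,
)


@pytest.fixture(scope="module")
def bimodal_prior():
    # two steep CDF rises separated by a flat stretch: a severely
    # bimodal density with a near-empty valley
    knots = [0.0] * 3 + [0.15, 0.2, 0.8, 0.85] + [1.0] * 3
    coefs = [0.0, 0.25, 0.5, 0.5, 0.75, 1.0, 1.0]
    return BSplinePrior(degree=2, knots=knots, coefficients=coefs, phi=1.0)


class TestPosterior:
    def test_conjugate_update(self, beta_informative):
        post = posterior(beta_informative, 10, 3)
        assert (post.alpha, post.beta) == (11.0, 29.0)
        ref = stats.beta(11, 29)
        g = np.linspace(0.01, 0.99, 199)
        assert np.max(np.abs(post.density(g) - ref.pdf(g))) < 1e-8
        assert np.max(np.abs(post.cdf(g) - ref.cdf(g))) < 1e-12

    def test_no_data_returns_the_prior(self, bspline_low):
        post = posterior(bspline_low, 0, 0)
        g = np.linspace(0, 1, 301)
        assert np.allclose(post.density(g), bspline_low.density(g), atol=1e-8)

    def test_quadrature_path_matches_conjugacy(self):
        prior = BetaPrior(8, 22)
        for n, x in [(20, 5), (40, 0), (15, 15)]:
            num = posterior(prior, n, x, method="quadrature")
            ref = posterior(prior, n, x)
            g = np.linspace(1e-4, 1 - 1e-4, 501)
            assert np.max(np.abs(num.density(g) - ref.density(g))) < 1e-6
            assert np.max(np.abs(num.cdf(g) - ref.cdf(g))) < 1e-6
            assert num.normalizer == pytest.approx(ref.normalizer, rel=1e-8)

    def test_numeric_posterior_normalized(self, bspline_low):
        post = posterior(bspline_low, 20, 5)
        total, _ = integrate.quad(post.density, 0, 1, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_data_rejected(self, beta_informative):
        with pytest.raises(ValueError):
            posterior(beta_informative, 10, 11)


class TestPredictive:
    def test_flat_prior_gives_uniform_predictive(self):
        pred = predictive_pmf(BetaPrior(1, 1), 5)
        assert np.allclose(pred.pmf, 1.0 / 6.0, atol=1e-12)

    def test_closed_form_small_case(self, beta_informative):
        pred = predictive_pmf(beta_informative, 2)
        assert pred.pmf[0] == pytest.approx(506.0 / 930.0, abs=1e-12)

    @pytest.mark.parametrize("n", [0, 1, 17])
    def test_normalization(self, n, beta_informative, bspline_low):
        for prior in (beta_informative, bspline_low):
            pred = predictive_pmf(prior, n, method="quadrature")
            assert pred.pmf.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(pred.pmf >= 0)

    def test_quadrature_matches_beta_binomial(self, beta_informative):
        for n in (5, 30):
            num = predictive_pmf(beta_informative, n, method="quadrature")
            ref = predictive_pmf(beta_informative, n)
            assert np.max(np.abs(num.pmf - ref.pmf)) < 1e-8

    def test_monte_carlo_two_stage_agreement(self, bspline_low, rng):
        n, draws = 10, 100_000
        thetas = bspline_low.sample(draws, rng)
        xs = rng.binomial(n, thetas)
        counts = np.bincount(xs, minlength=n + 1) / draws
        pred = predictive_pmf(bspline_low, n)
        se = np.sqrt(pred.pmf * (1 - pred.pmf) / draws)
        assert np.all(np.abs(counts - pred.pmf) <= 3 * se + 1e-12)


class TestHpdFixedLength:
    def test_full_length_covers_everything(self, beta_informative):
        iv = hpd_fixed_length(posterior(beta_informative, 4, 1), 1.0)
        assert iv.coverage == pytest.approx(1.0)
        assert iv.lower == 0.0

    def test_monotone_tail_anchors_at_zero(self):
        post = posterior(BetaPrior(1, 1), 75, 0)  # Beta(1, 76)
        iv = hpd_fixed_length(post, 0.1)
        assert iv.lower == pytest.approx(0.0, abs=1e-9)
        assert iv.coverage == pytest.approx(1 - 0.9**76, abs=1e-9)
        assert iv.is_hpd

    def test_symmetric_posterior_centred(self):
        post = posterior(BetaPrior(47, 47), 0, 0)
        iv = hpd_fixed_length(post, 0.2)
        assert iv.lower == pytest.approx(0.4, abs=1e-4)

    def test_coverage_monotone_in_length(self, beta_informative):
        post = posterior(beta_informative, 12, 4)
        covs = [
            hpd_fixed_length(post, l).coverage
            for l in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert covs == sorted(covs)

    def test_severely_multimodal_rejected(self, bimodal_prior):
        assert bimodal_prior.modality == "severe"
        post = posterior(bimodal_prior, 0, 0)
        with pytest.raises(MultimodalDensityError):
            hpd_fixed_length(post, 0.2)


class TestHpdFixedCoverage:
    def test_full_coverage_is_whole_domain(self, beta_informative):
        iv = hpd_fixed_coverage(posterior(beta_informative, 4, 1), 1.0)
        assert (iv.lower, iv.length) == (0.0, 1.0)

    def test_symmetric_case(self):
        iv = hpd_fixed_coverage(posterior(BetaPrior(2, 2), 0, 0), 0.95)
        assert iv.lower + iv.length / 2 == pytest.approx(0.5, abs=1e-6)

    def test_monotone_tail_closed_form(self):
        iv = hpd_fixed_coverage(posterior(BetaPrior(1, 1), 75, 0), 0.95)
        assert iv.lower == pytest.approx(0.0, abs=1e-9)
        assert iv.length == pytest.approx(1 - 0.05 ** (1 / 76.0), abs=1e-8)
        assert iv.is_hpd

    def test_length_monotone_in_coverage(self, beta_informative):
        post = posterior(beta_informative, 12, 4)
        lens = [
            hpd_fixed_coverage(post, c).length
            for c in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert lens == sorted(lens)

    def test_interior_interval_has_equal_endpoint_densities(
        self, beta_informative
    ):
        post = posterior(beta_informative, 30, 9)
        iv = hpd_fixed_coverage(post, 0.9)
        assert iv.is_hpd
        assert post.density(iv.lower) == pytest.approx(
            post.density(iv.upper), rel=1e-4
        )


class TestBruteForceOracle:
    def test_fifty_random_beta_cases(self, rng):
        for _ in range(50):
            a = rng.uniform(1.2, 40.0)
            b = rng.uniform(1.2, 40.0)
            n = int(rng.integers(0, 60))
            x = int(rng.integers(0, n + 1))
            post = posterior(BetaPrior(a, b), n, x)
            l = float(rng.uniform(0.05, 0.5))
            iv = hpd_fixed_length(post, l)
            b_lo, b_cov = oracles.brute_hpd_fixed_length(
                post.alpha, post.beta, l
            )
            assert abs(iv.lower - b_lo) < 2e-4
            assert abs(iv.coverage - b_cov) < 1e-4
            cov = float(rng.uniform(0.5, 0.99))
            iv2 = hpd_fixed_coverage(post, cov)
            b_lo2, b_len2 = oracles.brute_hpd_fixed_coverage(
                post.alpha, post.beta, cov
            )
            assert abs(iv2.lower - b_lo2) < 2e-4
            assert abs(iv2.length - b_len2) < 2e-4

    def test_numeric_path_against_beta_oracle(self):
        prior = BetaPrior(5, 9)
        post = posterior(prior, 18, 6, method="quadrature")
        iv = hpd_fixed_length(post, 0.25)
        b_lo, b_cov = oracles.brute_hpd_fixed_length(11, 21, 0.25)
        assert abs(iv.lower - b_lo) < 2e-4
        assert abs(iv.coverage - b_cov) < 1e-4
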