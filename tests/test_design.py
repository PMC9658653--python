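import numpy as np
import pytest

import oracles
from hpdsize import (
    BetaPrior,
    DesignSpec,
    average_coverage,
    average_length,
    default_search_bounds,
    discount_beta,
    frequentist_n,
    gacc,
    galc,
    gwoc,
    hpd_fixed_length,
    posterior,
    resample_expected_successes,
    search_optimal_n,
    worst_outcome_subset,
)


class TestFrequentist:
    @pytest.mark.parametrize(
        "p, expected", [(0.2625, 75), (0.5, 97), (0.26, 74)]
    )
    def test_precision_sample_sizes(self, p, expected):
        assert frequentist_n(p, l=0.2, level=0.95) == expected

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            frequentist_n(1.2)


class TestWorstOutcomeSubset:
    @pytest.mark.parametrize(
        "n, c, d, expected",
        [
            (45, 8, 22, [29, 30]),  # n+c+d odd: both candidates
            (46, 8, 22, [30]),      # even
            (10, 8, 22, [10]),      # n below |d−c|
            (100, 1, 1, [50]),      # flat prior: central outcome
            (101, 1, 1, [50, 51]),
        ],
    )
    def test_piecewise_rule(self, n, c, d, expected):
        assert worst_outcome_subset(n, c, d) == expected

    def test_non_integer_counts_give_bracketing_candidates(self):
        xs = worst_outcome_subset(50, 4.5, 11.5)
        assert xs == [28, 29]  # floor/ceil of (50+16)/2 − 4.5 = 28.5

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            worst_outcome_subset(10, 0, 5)


class TestResampling:
    def test_deterministic_given_seed(self, beta_informative):
        c1 = resample_expected_successes(beta_informative, 50, seed=7)
        c2 = resample_expected_successes(beta_informative, 50, seed=7)
        assert c1 == c2

    def test_concentrated_prior_recovers_its_mean(self):
        tight = BetaPrior(0.26 * 4000, 0.74 * 4000)
        c = resample_expected_successes(tight, 100, seed=11)
        assert abs(c - 26) <= 2

    def test_flat_prior_centers_at_half(self):
        cs = [
            resample_expected_successes(BetaPrior(1, 1), 100, seed=s)
            for s in range(10)
        ]
        assert abs(np.median(cs) - 50) <= 3


class TestSearchPolicy:
    def test_bounds_around_frequentist_estimate(self):
        assert default_search_bounds(75) == (38, 113)

    def test_trivial_criterion_returns_lower_bound(self):
        n, curve, expanded = search_optimal_n(lambda n: (True, 1.0), (5, 20))
        assert (n, expanded) == (5, False)
        assert curve == {5: 1.0}

    def test_matches_exhaustive_scan_for_monotone_criterion(self):
        threshold = 37

        def meets(n):
            return n >= threshold, float(n)

        n, _, expanded = search_optimal_n(meets, (10, 100))
        exhaustive = next(n for n in range(1, 201) if n >= threshold)
        assert n == exhaustive and not expanded

    def test_expansion_and_failure_are_flagged(self):
        n, _, expanded = search_optimal_n(lambda n: (n >= 30, 0.0), (10, 20))
        assert (n, expanded) == (30, True)
        n2, _, expanded2 = search_optimal_n(lambda n: (False, 0.0), (10, 20))
        assert n2 is None and expanded2


class TestCriteriaAgainstBruteForce:
    """Toy-case equivalence: small n, coarse targets, full enumeration."""

    def test_gacc_matches_enumeration(self):
        prior = BetaPrior(2, 2)
        spec = DesignSpec(prior, length=0.55, coverage=0.9,
                          search_bounds=(1, 10))
        res = gacc(spec)
        brute = next(
            (n for n in range(1, 11)
             if oracles.brute_average_coverage(2, 2, n, 0.55) >= 0.9),
            None,
        )
        assert res.n_opt == brute
        for n, val in res.curve.items():
            assert val == pytest.approx(
                oracles.brute_average_coverage(2, 2, n, 0.55), abs=1e-4
            )

    def test_galc_matches_enumeration(self):
        prior = BetaPrior(2, 2)
        spec = DesignSpec(prior, length=0.55, coverage=0.9,
                          search_bounds=(1, 10))
        res = galc(spec)
        brute = next(
            (n for n in range(1, 11)
             if oracles.brute_average_length(2, 2, n, 0.9) <= 0.55),
            None,
        )
        assert res.n_opt == brute
        for n, val in res.curve.items():
            assert val == pytest.approx(
                oracles.brute_average_length(2, 2, n, 0.9), abs=2e-4
            )

    def test_gwoc_full_space_matches_enumeration(self):
        prior = BetaPrior(2, 2)
        spec = DesignSpec(prior, length=0.55, coverage=0.9,
                          search_bounds=(1, 10), woc_space="full")
        res = gwoc(spec)
        brute = next(
            (n for n in range(1, 11)
             if oracles.brute_worst_coverage(2, 2, n, 0.55) >= 0.9),
            None,
        )
        assert res.n_opt == brute


class TestGwoc:
    def test_flat_prior_formula_attains_the_minimum(self):
        # the closed-form x* must be the worst outcome over the whole
        # data space for the flat prior
        prior = BetaPrior(1, 1)
        for n in range(2, 61, 7):
            xs = worst_outcome_subset(n, 1.0, 1.0)
            worst_formula = min(
                hpd_fixed_length(posterior(prior, n, x), 0.2).coverage
                for x in xs
            )
            worst_full = min(
                hpd_fixed_length(posterior(prior, n, x), 0.2).coverage
                for x in range(n + 1)
            )
            assert worst_formula == pytest.approx(worst_full, abs=1e-9)

    def test_flat_prior_threshold_matches_central_posterior(self):
        # GWOC for the flat prior is governed by the central outcome
        spec = DesignSpec(BetaPrior(1, 1), length=0.2, coverage=0.95,
                          search_bounds=(80, 113))
        res = gwoc(spec)
        n = res.n_opt
        central = hpd_fixed_length(
            posterior(BetaPrior(1, 1), n, n // 2), 0.2
        ).coverage
        below = min(
            hpd_fixed_length(posterior(BetaPrior(1, 1), n - 1, x), 0.2).coverage
            for x in worst_outcome_subset(n - 1, 1, 1)
        )
        assert central >= 0.95 > below

    def test_variants_agree_on_symmetric_flat_prior(self):
        results = {
            ws: gwoc(DesignSpec(BetaPrior(1, 1), search_bounds=(85, 113),
                                woc_space=ws, seed=3)).n_opt
            for ws in ("formula", "full", "predictive-band")
        }
        assert len(set(results.values())) == 1


class TestCurveShapes:
    def test_average_coverage_nondecreasing_in_n(self, beta_informative):
        vals = [average_coverage(beta_informative, n, 0.2)
                for n in range(38, 50)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_average_length_nonincreasing_in_n(self, beta_informative):
        vals = [average_length(beta_informative, n, 0.95)
                for n in range(38, 50)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_informative_priors_never_need_more_patients(self):
        # d0 = 1 / 0.5 / 0 from the worked example's kernel counts
        sizes = {}
        for d0 in (1.0, 0.5, 0.0):
            prior = discount_beta(7, 21, d0)
            sizes[d0] = {
                "gacc": gacc(DesignSpec(prior, search_bounds=(38, 113))).n_opt,
                "galc": galc(DesignSpec(prior, search_bounds=(38, 113))).n_opt,
            }
        for crit in ("gacc", "galc"):
            assert sizes[1.0][crit] <= sizes[0.5][crit] <= sizes[0.0][crit]

    def test_criterion_ordering_galc_gacc_gwoc(self):
        for prior in (BetaPrior(8, 22), BetaPrior(4.5, 11.5), BetaPrior(1, 1)):
            spec = lambda ws="formula": DesignSpec(
                prior, search_bounds=(38, 113), woc_space=ws, seed=1
            )
            n_galc = galc(spec()).n_opt
            n_gacc = gacc(spec()).n_opt
            n_gwoc = gwoc(spec()).n_opt
            assert n_galc <= n_gacc <= n_gwoc
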