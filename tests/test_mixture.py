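"""Discrimination mixture model: likelihood, posterior, membership, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import cardiorivalry as cr
from cardiorivalry.mixture import (
    MixturePosterior,
    hdi,
    posterior_predictive_pmf,
)


def _disc_table(k, n=120):
    k = np.asarray(k)
    return pd.DataFrame({"subject": np.arange(k.size), "k": k, "n": n})


class TestAboveChanceLikelihood:
    def test_normalization(self):
        total = sum(
            cr.above_chance_likelihood(k, 120, 2.0, 3.0) for k in range(121)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("k", [60, 80, 100])
    def test_monte_carlo_oracle_uniform_b(self, k):
        # alpha = beta = 1: accuracy uniform on [0.5, 1]
        rng = np.random.default_rng(100 + k)
        n_mc = 1_000_000
        p = 0.5 + 0.5 * rng.random(n_mc)
        vals = stats.binom.pmf(k, 120, p)
        mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n_mc)
        assert cr.above_chance_likelihood(k, 120, 1.0, 1.0) == pytest.approx(
            mc, abs=3 * se
        )

    def test_quadrature_oracle(self):
        for a, b, k in [(2, 3, 70), (0.5, 0.5, 90), (5, 1, 110)]:
            f = lambda x: stats.binom.pmf(k, 120, 0.5 + x / 2) * stats.beta.pdf(
                x, a, b
            )
            q, _ = integrate.quad(f, 0, 1, limit=200)
            assert cr.above_chance_likelihood(k, 120, a, b) == pytest.approx(
                q, abs=1e-8
            )

    def test_concentration_near_perfect_accuracy(self):
        # alpha/(alpha+beta) -> 1 with large alpha+beta: mass piles at k = n
        probs = [cr.above_chance_likelihood(k, 120, 200.0, 1.0) for k in range(121)]
        assert np.argmax(probs) > 110

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cr.above_chance_likelihood(10, 120, -1.0, 2.0)
        with pytest.raises(ValueError):
            cr.above_chance_likelihood(121, 120, 1.0, 2.0)


class TestFitMixture:
    def test_deterministic_under_seed(self):
        tab = _disc_table([55, 60, 62, 58, 90, 61, 57, 65])
        p1 = cr.fit_mixture(tab, n_draws=500, seed=4)
        p2 = cr.fit_mixture(tab, n_draws=500, seed=4)
        np.testing.assert_array_equal(p1.prevalence, p2.prevalence)
        np.testing.assert_array_equal(p1.membership, p2.membership)

    def test_saturated_evidence(self):
        tab = _disc_table([120] * 8)
        post = cr.fit_mixture(tab, n_draws=2000, seed=1)
        assert post.prevalence.mean() > 0.9

    def test_chance_reduction_identity(self):
        # with prevalence pinned to ~0 the mixture likelihood must reduce
        # to the pure Binomial(n, 0.5) likelihood
        k, n = 60, 120
        la = cr.above_chance_likelihood(k, n, 2.0, 4.0)
        chance = stats.binom.pmf(k, n, 0.5)
        assert 0.0 * la + 1.0 * chance == pytest.approx(chance)

    def test_posterior_predictive_sums_to_one(self):
        tab = _disc_table([55, 60, 62, 58, 90, 61])
        post = cr.fit_mixture(tab, n_draws=800, seed=2)
        pmf = posterior_predictive_pmf(post)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mcmc_backend_agrees_loosely(self):
        tab = _disc_table([55, 60, 62, 58, 90, 61, 57, 65, 70, 85])
        g = cr.fit_mixture(tab, n_draws=2000, seed=3)
        m = cr.fit_mixture(tab, n_draws=2000, seed=3, backend="mcmc")
        assert abs(g.prevalence.mean() - m.prevalence.mean()) < 0.15
        assert "rhat" in m.diagnostics

    def test_mismatched_trial_counts_rejected(self):
        tab = pd.DataFrame({"subject": [0, 1], "k": [50, 60], "n": [120, 100]})
        with pytest.raises(ValueError):
            cr.fit_mixture(tab)


class TestMembership:
    def test_single_draw_closed_form(self):
        # a posterior with one repeated draw must reproduce the Bayes ratio
        pi, a, b, n, k = 0.1, 2.0, 4.0, 120, 85
        post = MixturePosterior(
            prevalence=np.full(10, pi), alpha=np.full(10, a), beta=np.full(10, b),
            k=np.array([k]), n=n, membership=np.empty(0),
            backend="grid", converged=True,
        )
        la = cr.above_chance_likelihood(k, n, a, b)
        expected = pi * la / (pi * la + (1 - pi) * stats.binom.pmf(k, n, 0.5))
        assert cr.membership_probability(k, post) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_prevalence_zero_membership(self):
        post = MixturePosterior(
            prevalence=np.zeros(5), alpha=np.full(5, 2.0), beta=np.full(5, 4.0),
            k=np.array([80]), n=120, membership=np.empty(0),
            backend="grid", converged=True,
        )
        assert cr.membership_probability(100, post) == 0.0

    def test_monotone_in_k_above_chance(self):
        tab = _disc_table([55, 60, 62, 58, 90, 61, 70, 75])
        post = cr.fit_mixture(tab, n_draws=1000, seed=5)
        probs = [cr.membership_probability(k, post) for k in range(60, 121, 5)]
        assert np.all(np.diff(probs) >= -1e-12)


class TestScreening:
    def test_threshold_one_retains_everyone(self):
        tab = _disc_table([55, 60, 90, 62])
        post = cr.fit_mixture(tab, n_draws=500, seed=6)
        kept, cutoff = cr.screen_at_chance(tab, post, threshold=1.0)
        assert len(kept) == 4
        assert cutoff == pytest.approx(90 / 120)

    def test_retained_set_downward_closed(self):
        ks = np.arange(50, 101, 5)
        tab = _disc_table(ks)
        post = cr.fit_mixture(tab, n_draws=1000, seed=7)
        kept, _ = cr.screen_at_chance(tab, post, threshold=0.05)
        kept_k = np.sort(tab.set_index("subject").loc[kept, "k"].to_numpy())
        if kept_k.size:
            # every observed k below the largest retained k is retained
            assert set(ks[ks <= kept_k.max()]) == set(kept_k)

    def test_near_perfect_scorer_never_retained(self):
        cfg = cr.CohortConfig()
        tab = cr.simulate_discrimination(cfg, seed=11)[["subject", "k", "n"]].copy()
        tab.loc[0, "k"] = 119
        post = cr.fit_mixture(tab, n_draws=2000, seed=8)
        kept, _ = cr.screen_at_chance(tab, post, threshold=0.05)
        assert 0 not in set(kept)


class TestBinomialScreen:
    def test_chance_level_not_significant(self):
        p, flag = cr.binomial_above_chance(60, 120)
        assert p == pytest.approx(0.5363, abs=5e-4)
        assert not flag

    def test_perfect_score_closed_form(self):
        p, flag = cr.binomial_above_chance(120, 120)
        assert p == pytest.approx(0.5**120, rel=1e-9)
        assert flag

    def test_monotone_decreasing_in_k(self):
        ps = np.array([cr.binomial_above_chance(k, 120)[0] for k in range(121)])
        assert np.all(np.diff(ps) <= 0)
        # strict wherever the tail is numerically resolvable from 1
        mid = ps[40:111]
        assert np.all(np.diff(mid) < 0)


class TestHDI:
    def test_shortest_interval_on_skewed_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(2.0, 1.0, 20_000)
        lo, hi = hdi(draws, 0.95)
        eq = np.percentile(draws, [2.5, 97.5])
        assert hi - lo <= eq[1] - eq[0]
        assert np.mean((draws >= lo) & (draws <= hi)) >= 0.95 - 1e-3
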