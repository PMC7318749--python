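"""Conjugate posterior updates and the probability of superiority.

The closed-form machinery is cross-checked against three independent
oracles: brute-force numerical normalization of prior x likelihood on a
rate grid, paired Monte-Carlo sampling from the Gamma posteriors, and
one-dimensional quadrature of the rate-ordering integral.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from probio_sim.weibull_bayes import (
    PosteriorState,
    PriorSpec,
    SurvivalData,
    mean_pfs,
    posterior_draws,
    posterior_update,
    prob_superiority,
    rate_for_mean,
)


# -- independent oracles ---------------------------------------------------


def brute_force_posterior_density(prior, data, grid):
    """Unnormalized prior x Weibull likelihood, numerically normalized."""
    k = prior.shape_k
    log_post = stats.gamma.logpdf(grid, a=prior.alpha, scale=1.0 / prior.beta)
    for t in data.event_times:
        # Weibull density with rate lam: k*lam*t^(k-1) * exp(-lam t^k)
        log_post += np.log(k * grid * t ** (k - 1)) - grid * t**k
    for t in data.censor_times:
        log_post += -grid * t**k
    dens = np.exp(log_post - log_post.max())
    return dens / np.trapezoid(dens, grid)


def mc_prob_superiority(post_t, post_c, n=1_000_000, seed=0):
    rng = np.random.default_rng(seed)
    lt = rng.gamma(post_t.alpha_post, 1.0 / post_t.beta_post, size=n)
    lc = rng.gamma(post_c.alpha_post, 1.0 / post_c.beta_post, size=n)
    return float((lt < lc).mean())


def quadrature_prob_superiority(post_t, post_c):
    """P(lam_t < lam_c) = integral of F_t(x) f_c(x) dx."""
    f_c = stats.gamma(a=post_c.alpha_post, scale=1.0 / post_c.beta_post)
    f_t = stats.gamma(a=post_t.alpha_post, scale=1.0 / post_t.beta_post)
    lo, hi = f_c.ppf(1e-14), f_c.ppf(1 - 1e-14)
    val, err = integrate.quad(
        lambda x: f_t.cdf(x) * f_c.pdf(x),
        lo,
        hi,
        limit=400,
        epsabs=1e-11,
        epsrel=1e-11,
    )
    assert err < 1e-8
    return val


# -- posterior update ------------------------------------------------------


class TestPosteriorUpdate:
    def test_empty_data_returns_prior(self):
        post = posterior_update(PriorSpec(), SurvivalData())
        assert (post.alpha_post, post.beta_post) == (10, 80)

    @pytest.mark.parametrize(
        "k, events, censored, expected",
        [
            (1.0, (2, 4, 6), (5,), (13, 97)),
            (2.0, (3,), (), (11, 89)),
        ],
    )
    def test_hand_computable_updates(self, k, events, censored, expected):
        post = posterior_update(
            PriorSpec(shape_k=k), SurvivalData(events, censored)
        )
        assert (post.alpha_post, post.beta_post) == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData(event_times=[0.0])
        with pytest.raises(ValueError):
            SurvivalData(censor_times=[-1.0])

    def test_prior_pseudo_event_count_is_preserved(self, rng):
        """alpha_post - n_events always equals the prior's 10 pseudo-events."""
        for _ in range(20):
            data = SurvivalData(
                rng.exponential(8, size=rng.integers(0, 10)),
                rng.exponential(8, size=rng.integers(0, 10)),
            )
            post = posterior_update(PriorSpec(), data)
            assert post.alpha_post - post.n_events == 10

    def test_conjugacy_matches_brute_force_normalization(self, rng):
        """On random small datasets the closed-form Gamma posterior equals
        the numerically normalized prior x likelihood (TV distance < 1e-6)."""
        grid = np.linspace(1e-4, 1.5, 40_000)
        for k in (1.0, 1.7):
            prior = PriorSpec(shape_k=k)
            for _ in range(10):
                data = SurvivalData(
                    rng.exponential(8, size=rng.integers(1, 6)),
                    rng.exponential(8, size=rng.integers(0, 6)),
                )
                post = posterior_update(prior, data)
                closed = stats.gamma.pdf(
                    grid, a=post.alpha_post, scale=1.0 / post.beta_post
                )
                brute = brute_force_posterior_density(prior, data, grid)
                tv = 0.5 * np.trapezoid(np.abs(closed - brute), grid)
                assert tv < 1e-6

    def test_posterior_mean_recovers_true_rate(self):
        """With 2000 events at true rate 1/8 the posterior mean lands within
        5% relative error."""
        rng = np.random.default_rng(11)
        true_lam = 0.125
        data = SurvivalData(rng.exponential(1 / true_lam, size=2000))
        post = posterior_update(PriorSpec(), data)
        assert abs(post.mean_rate - true_lam) / true_lam < 0.05


# -- mean <-> rate ---------------------------------------------------------


class TestMeanRate:
    @pytest.mark.parametrize(
        "lam, k, expected",
        [(0.125, 1.0, 8.0), (1.0, 1.0, 1.0), (1.0, 2.0, math.gamma(1.5))],
    )
    def test_mean_pfs_closed_form(self, lam, k, expected):
        assert mean_pfs(lam, k) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "mean, k, expected", [(8.0, 1.0, 0.125), (math.gamma(1.5), 2.0, 1.0)]
    )
    def test_rate_for_mean_inverts(self, mean, k, expected):
        assert rate_for_mean(mean, k) == pytest.approx(expected, abs=1e-12)

    @given(
        mean=st.floats(0.1, 100.0),
        k=st.floats(0.5, 3.0),
    )
    def test_round_trip_property(self, mean, k):
        assert mean_pfs(rate_for_mean(mean, k), k) == pytest.approx(
            mean, rel=1e-10
        )

    def test_mean_pfs_decreasing_in_rate(self):
        rates = np.linspace(0.01, 2.0, 50)
        means = [mean_pfs(r, 1.3) for r in rates]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            mean_pfs(0.0, 1.0)
        with pytest.raises(ValueError):
            rate_for_mean(-3.0, 1.0)


# -- probability of superiority -------------------------------------------


class TestProbSuperiority:
    def test_identical_posteriors_give_half(self):
        post = PosteriorState(10, 80)
        assert prob_superiority(post, post) == pytest.approx(0.5, abs=1e-15)

    def test_matches_million_draw_monte_carlo(self):
        """Doubled exposure at equal events: closed form I_{2/3}(10, 10)
        agrees with a 1e6-draw Monte-Carlo oracle within 0.002."""
        t = PosteriorState(10, 160)
        c = PosteriorState(10, 80)
        closed = prob_superiority(t, c)
        assert abs(closed - mc_prob_superiority(t, c, seed=5)) < 0.002

    def test_matches_quadrature(self):
        t = PosteriorState(13, 97)
        c = PosteriorState(10, 80)
        assert prob_superiority(t, c) == pytest.approx(
            quadrature_prob_superiority(t, c), abs=1e-6
        )

    @given(
        a_t=st.floats(1.0, 200.0),
        b_t=st.floats(1.0, 2000.0),
        a_c=st.floats(1.0, 200.0),
        b_c=st.floats(1.0, 2000.0),
    )
    def test_complementarity(self, a_t, b_t, a_c, b_c):
        t = PosteriorState(a_t, b_t)
        c = PosteriorState(a_c, b_c)
        assert prob_superiority(t, c) + prob_superiority(c, t) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_in_exposure_and_events(self):
        c = PosteriorState(10, 80)
        # more exposure at fixed events -> lower rate -> higher superiority
        betas = np.linspace(60, 300, 30)
        ps = [prob_superiority(PosteriorState(12, b), c) for b in betas]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        # more events at fixed exposure -> higher rate -> lower superiority
        alphas = np.arange(5, 40)
        ps = [prob_superiority(PosteriorState(a, 120), c) for a in alphas]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_mismatched_shape_rejected(self):
        with pytest.raises(ValueError):
            prob_superiority(
                PosteriorState(10, 80, shape_k=1.0),
                PosteriorState(10, 80, shape_k=2.0),
            )


class TestPosteriorDraws:
    def test_reproducible_and_moment_correct(self):
        post = PosteriorState(13, 97)
        a = posterior_draws(post, 1_000_000, seed=3)
        b = posterior_draws(post, 1_000_000, seed=3)
        assert np.array_equal(a, b)
        se = math.sqrt(post.alpha_post) / post.beta_post / 1000
        assert abs(a.mean() - post.mean_rate) < 3 * se

    def test_empirical_superiority_matches_closed_form(self):
        t = PosteriorState(25, 300)
        c = PosteriorState(18, 150)
        closed = prob_superiority(t, c)
        emp = mc_prob_superiority(t, c, n=400_000, seed=9)
        assert abs(emp - closed) < 3 * math.sqrt(closed * (1 - closed) / 400_000)

    def test_json_roundtrip(self):
        post = PosteriorState(13, 97, n_events=3, n_subjects=4)
        assert PosteriorState.from_json(post.to_json()) == post
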