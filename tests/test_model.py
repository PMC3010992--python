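import math

import numpy as np
import pytest
from scipy import stats

from navcoc.model import (
    CircleOfConfusionModel,
    MCMCConfig,
    PosteriorSamples,
    PriorSpec,
    coc_interval,
    coc_radius,
    log_joint,
    predictive_coc,
    summarize,
)
from navcoc.simulate import SimulationSpec, simulate_deviations, simulate_population
from navcoc.validation import gaussian_marginal_loglik


def mvn_marginal_loglik(y, gamma, sigma, sigma_eps, m0, V0):
    """Closed-form marginal likelihood via the joint MVN of the latent AR(1).

    Independent of the Kalman recursion: builds mean and covariance of x
    explicitly from the linear structure and evaluates the dense MVN.
    """
    T = len(y)
    mean = np.array([m0 * gamma**t for t in range(T)])
    cov = np.empty((T, T))
    for t in range(T):
        for s in range(T):
            c = gamma ** (t + s) * V0
            c += sigma**2 * sum(gamma ** (t - k) * gamma ** (s - k) for k in range(1, min(t, s) + 1))
            cov[t, s] = c
    cov += np.eye(T) * sigma_eps**2
    return stats.multivariate_normal.logpdf(y, mean=mean, cov=cov)


class TestCocRadius:
    def test_white_noise_case(self):
        assert coc_radius(5.0, 0.0) == pytest.approx(5.0)

    def test_high_autocorrelation(self):
        assert coc_radius(13.6, 0.99) == pytest.approx(13.6 / math.sqrt(1 - 0.99**2), rel=1e-12)
        assert coc_radius(13.6, 0.99) == pytest.approx(96.4, abs=0.05)

    def test_boundary(self):
        assert np.isfinite(coc_radius(1.0, 0.999999))
        with pytest.raises(ValueError):
            coc_radius(1.0, 1.0)
        with pytest.raises(ValueError):
            coc_radius(-1.0, 0.5)


class TestCocInterval:
    def test_95_percent(self):
        assert coc_interval(100.0, 0.95) == pytest.approx(195.9964, abs=1e-3)

    def test_one_sigma(self):
        assert coc_interval(100.0, 0.6826895) == pytest.approx(100.0, abs=0.01)

    def test_monotone_in_level(self):
        widths = [coc_interval(50.0, l) for l in (0.5, 0.8, 0.9, 0.99)]
        assert widths == sorted(widths)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            coc_interval(10.0, 1.5)


class TestLogJoint:
    priors = PriorSpec()

    def params(self, **kw):
        base = dict(
            gamma=[0.5], sigma=[2.0], x=[np.array([0.2, 0.8, -0.1])],
            a=3.0, b=2.0, theta=5.0, tau=10.0, nu=4.0, sigma_eps=2.0,
        )
        base.update(kw)
        return base

    def test_matches_hand_computation(self):
        y = np.array([0.0, 1.0, 0.0])
        p = self.params()
        got = log_joint(p, [y], self.priors, init_state=("fixed", 0.0, 5.0))
        x = p["x"][0]
        want = 0.0
        # 3 observation terms + initial state
        want += stats.norm.logpdf(y, loc=x, scale=2.0).sum()
        want += stats.norm.logpdf(x[0], 0.0, 5.0)
        # 2 process terms (scaled t)
        e = x[1:] - 0.5 * x[:-1]
        want += stats.t.logpdf(e, df=4.0, scale=2.0).sum()
        # individual priors: transformed beta on gamma, truncated normal on sigma
        want += stats.beta.logpdf((0.5 + 1) / 2, 3.0, 2.0) - math.log(2.0)
        want += stats.norm.logpdf(2.0, 5.0, 10.0) - stats.norm.logsf(0.0, 5.0, 10.0)
        # sigma_eps truncated-normal prior and uniform hyper-priors
        want += stats.norm.logpdf(2.0, 2.0, 0.02) - stats.norm.logsf(0.0, 2.0, 0.02)
        for lo, hi in (self.priors.a_range, self.priors.b_range,
                       self.priors.theta_range, self.priors.tau_range):
            want -= math.log(hi - lo)
        want -= math.log(self.priors.nu_range[1] - self.priors.nu_range[0])
        assert got == pytest.approx(want, abs=1e-10)

    def test_t_converges_to_normal(self):
        y = np.array([0.0, 1.0, 0.0])
        lp_t = log_joint(self.params(nu=1e6), [y], PriorSpec(nu_range=(1.5, 1e7)),
                         init_state=("fixed", 0.0, 5.0))
        lp_n = log_joint(self.params(nu=math.inf), [y], PriorSpec(nu_range=(1.5, 1e7)),
                         init_state=("fixed", 0.0, 5.0))
        # remove the uniform nu prior term present only in the finite case
        lp_t += math.log(1e7 - 1.5)
        assert lp_t == pytest.approx(lp_n, abs=1e-3)

    def test_outside_support_is_minus_inf(self):
        y = np.array([0.0, 1.0, 0.0])
        assert log_joint(self.params(gamma=[1.5]), [y], self.priors) == -math.inf
        assert log_joint(self.params(sigma=[-1.0]), [y], self.priors) == -math.inf

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            log_joint(self.params(), [np.zeros(5)], self.priors)


class TestGaussianMarginalLoglik:
    def test_matches_dense_mvn(self, rng):
        for _ in range(5):
            T = 8
            gamma = rng.uniform(-0.9, 0.95)
            sigma = rng.uniform(0.5, 3.0)
            sigma_eps = rng.uniform(0.2, 2.0)
            m0, V0 = rng.normal(), rng.uniform(0.5, 4.0)
            _, y = simulate_deviations(gamma, sigma, np.inf, sigma_eps, T, seed=rng)
            got = gaussian_marginal_loglik(y, gamma, sigma, sigma_eps, m0, V0)
            want = mvn_marginal_loglik(y, gamma, sigma, sigma_eps, m0, V0)
            assert got == pytest.approx(want, abs=1e-8)

    def test_matches_statsmodels_sarimax(self):
        # cross-check against an established Kalman implementation
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        gamma, sigma, sigma_eps = 0.8, 1.5, 0.0
        _, y = simulate_deviations(gamma, sigma, np.inf, 0.5, 60, seed=3)
        # stationary initialization: m0 = 0, V0 = sigma^2/(1-gamma^2)
        got = gaussian_marginal_loglik(
            y, gamma, sigma, 1e-8, 0.0, sigma**2 / (1 - gamma**2)
        )
        mod = SARIMAX(y, order=(1, 0, 0), trend="n")
        want = mod.loglike(np.array([gamma, sigma**2]))
        assert got == pytest.approx(want, rel=1e-6)


class TestProtocol:
    def test_default_retained_draws(self):
        assert MCMCConfig().n_retained == 8000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burnin=200)

    def test_fit_draw_count_and_reproducibility(self):
        pop = simulate_population(SimulationSpec(n_per_group=1, T=30, seed=4))
        kw = dict(grouping="common", n_chains=2, n_iter=400, n_burnin=200, thin=4, seed=11)
        m1 = CircleOfConfusionModel(**kw).fit(pop["series"])
        m2 = CircleOfConfusionModel(**kw).fit(pop["series"])
        assert m1.samples_.n_draws == 2 * (400 - 200) // 4
        np.testing.assert_array_equal(m1.samples_.gamma, m2.samples_.gamma)
        np.testing.assert_array_equal(m1.samples_.sigma_eps, m2.samples_.sigma_eps)

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            CircleOfConfusionModel().fit([np.zeros(3)])

    def test_missing_days_handled(self):
        _, y = simulate_deviations(0.9, 5.0, 4.0, 2.0, 40, seed=2)
        y[10:15] = np.nan
        m = CircleOfConfusionModel(
            n_chains=1, n_iter=300, n_burnin=100, thin=1, seed=0
        ).fit([y])
        assert np.all(np.isfinite(m.samples_.flat(m.samples_.coc)))

    def test_by_sex_grouping_shares_nu_and_eps(self):
        pop = simulate_population(SimulationSpec(n_per_group=2, T=30, seed=6))
        m = CircleOfConfusionModel(
            grouping="by_sex", n_chains=1, n_iter=300, n_burnin=100, thin=1, seed=0
        ).fit(pop["series"])
        s = m.samples_
        assert s.a.shape[-1] == 2 and s.theta.shape[-1] == 2
        assert s.nu.ndim == 2 and s.sigma_eps.ndim == 2  # single shared series
        assert s.group_names == ["female", "male"]


def make_samples(**arrays):
    """Minimal PosteriorSamples for summary/predictive unit tests."""
    C, D, J, G = 1, arrays["gamma"].shape[1], arrays["gamma"].shape[2], arrays["a"].shape[2]
    return PosteriorSamples(
        animal_ids=[f"T{j}" for j in range(J)],
        groups=np.zeros(J, dtype=int),
        group_names=["all"] if G == 1 else [str(g) for g in range(G)],
        **arrays,
    )


class TestSummaries:
    def test_quantile_rule(self):
        draws = np.arange(1.0, 101.0)[None, :, None]
        ones = np.ones_like(draws)
        s = make_samples(gamma=draws * 0, sigma=draws, a=ones, b=ones,
                         theta=ones, tau=ones, nu=np.ones((1, 100)),
                         sigma_eps=np.ones((1, 100)))
        table = summarize(s)
        row = table.loc["sigma[T0]"]
        assert row["2.5%"] == pytest.approx(3.475)
        assert row["50%"] == pytest.approx(50.5)
        assert row["97.5%"] == pytest.approx(97.525)

    def test_constant_draws_collapse(self):
        const = np.full((1, 50, 1), 7.0)
        ones = np.ones((1, 50, 1))
        s = make_samples(gamma=const * 0, sigma=const, a=ones, b=ones,
                         theta=ones, tau=ones, nu=np.ones((1, 50)),
                         sigma_eps=np.ones((1, 50)))
        row = summarize(s).loc["sigma[T0]"]
        assert row["2.5%"] == row["50%"] == row["97.5%"] == 7.0

    def test_row_per_parameter(self):
        pop = simulate_population(SimulationSpec(n_per_group=1, T=30, seed=4))
        m = CircleOfConfusionModel(
            n_chains=1, n_iter=300, n_burnin=100, thin=1, seed=0
        ).fit(pop["series"])
        # per group: coc_mean, coc_pred*, a, b, theta, tau; shared: sigma_eps,
        # nu; per animal: coc, gamma, sigma
        assert len(m.summary_) == 6 + 2 + 3 * 2


class TestPredictiveCoc:
    def test_draw_count_and_positivity(self):
        pop = simulate_population(SimulationSpec(n_per_group=2, T=30, seed=8))
        m = CircleOfConfusionModel(
            n_chains=1, n_iter=400, n_burnin=200, thin=2, seed=1
        ).fit(pop["series"])
        pred = m.predictive_coc(seed=0)
        assert len(pred) == m.samples_.n_draws
        assert np.all(pred > 0)

    def test_concentration_limit(self):
        # a = b -> gamma* ~ 0; tiny tau -> sigma* ~ theta; CoC* ~ theta
        C, D, J = 1, 2000, 1
        ones = np.ones((C, D, J))
        s = make_samples(
            gamma=ones * 0.5, sigma=ones, a=ones * 1e6, b=ones * 1e6,
            theta=ones * 5.0, tau=ones * 1e-3, nu=np.full((C, D), 4.0),
            sigma_eps=np.ones((C, D)),
        )
        pred = predictive_coc(s, seed=0)
        assert np.median(pred) == pytest.approx(5.0, rel=0.01)

    def test_non_hierarchical_rejected(self):
        pop = simulate_population(SimulationSpec(n_per_group=1, T=30, seed=4))
        m = CircleOfConfusionModel(
            hierarchical=False, fixed_hypers=dict(a=2, b=2, theta=0, tau=20),
            n_chains=1, n_iter=300, n_burnin=100, thin=1, seed=0,
        ).fit(pop["series"])
        with pytest.raises(ValueError):
            m.predictive_coc()

    def test_predictive_wider_than_mean_coc(self):
        # the induced distribution for a new animal carries between-animal
        # spread on top of hyper uncertainty
        pop = simulate_population(SimulationSpec(seed=10))
        m = CircleOfConfusionModel(
            n_chains=1, n_iter=1500, n_burnin=500, thin=2, seed=2,
            store_states=False,
        ).fit(pop["series"])
        pred = m.predictive_coc(seed=0)
        mean_coc = m.samples_.flat(m.samples_.coc_mean())
        iqr = lambda v: np.subtract(*np.percentile(v, [75, 25]))
        assert iqr(pred) > iqr(mean_coc)


class TestSamplerAgainstGrid:
    def test_posterior_medians_match_grid(self):
        # Gaussian special case: exact 2-D grid posterior vs MCMC medians
        from navcoc.validation import grid_posterior_gaussian

        _, y = simulate_deviations(0.9, 5.0, np.inf, 2.0, 50, seed=21)
        gg = np.linspace(0.3, 0.999, 140)
        sg = np.linspace(0.5, 15.0, 140)
        P = grid_posterior_gaussian(y, 2.0, 0.0, 100.0, gg, sg,
                                    prior_a=2, prior_b=2, prior_theta=0, prior_tau=20)
        med_g = gg[np.searchsorted(np.cumsum(P.sum(axis=1)), 0.5)]
        med_s = sg[np.searchsorted(np.cumsum(P.sum(axis=0)), 0.5)]
        m = CircleOfConfusionModel(
            hierarchical=False, fixed_hypers=dict(a=2, b=2, theta=0, tau=20),
            nu=np.inf, fixed_sigma_eps=2.0, init_state=("fixed", 0.0, 10.0),
            n_chains=2, n_iter=4000, n_burnin=1000, thin=1, seed=13,
            store_states=False,
        ).fit([y])
        g = np.median(m.samples_.flat(m.samples_.gamma))
        s = np.median(m.samples_.flat(m.samples_.sigma))
        assert g == pytest.approx(med_g, abs=0.02)
        assert s == pytest.approx(med_s, abs=0.3)

    def test_fixed_gamma_sigma_marginal_matches_grid(self):
        # gamma pinned at 0, Gaussian errors, known sigma_eps: the sigma
        # marginal from MCMC matches a dense-grid numerical posterior
        _, y = simulate_deviations(0.0, 4.0, np.inf, 1.0, 60, seed=31)
        sg = np.linspace(1.0, 10.0, 2000)
        logp = np.array([
            gaussian_marginal_loglik(y, 0.0, s, 1.0, 0.0, s**2)
            + stats.norm.logpdf(s, 0.0, 20.0)
            for s in sg
        ])
        p = np.exp(logp - logp.max())
        p /= p.sum()
        cdf_grid = np.cumsum(p)
        m = CircleOfConfusionModel(
            hierarchical=False, fixed_hypers=dict(a=2, b=2, theta=0, tau=20),
            nu=np.inf, fixed_gamma=0.0, fixed_sigma_eps=1.0,
            init_state=("stationary",),
            n_chains=2, n_iter=6000, n_burnin=1000, thin=1, seed=17,
            store_states=False,
        ).fit([y])
        draws = np.sort(m.samples_.flat(m.samples_.sigma)[:, 0])
        cdf_mcmc = np.searchsorted(draws, sg) / len(draws)
        ks = np.max(np.abs(cdf_mcmc - cdf_grid))
        assert ks < 0.05
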