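import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from clonaltiming import synthetic
from clonaltiming.incidence import (
    GammaPairPrior,
    SamplerConfig,
    WaitingTimePriors,
    censored_rejection_update,
    dirichlet_split_update,
    intervention_curves,
    lambda_update,
    run_gibbs,
    sample_cohort_from_curves,
    shape_rate_update,
    simulate_intervention,
)


class TestPriors:
    def test_informative_prior_in_log_space(self):
        ages = np.full(50, 100.0)
        prior = GammaPairPrior.from_observed_ages(ages)
        assert np.isfinite(prior.log_p)
        assert prior.log_p == pytest.approx(50 * np.log(100.0))
        assert prior.q == pytest.approx(5000.0)
        assert prior.r == prior.s == 50.0

    def test_rejects_nonpositive_ages(self):
        with pytest.raises(ValueError):
            GammaPairPrior.from_observed_ages([10.0, -1.0])


class TestCohortFromCurves:
    def test_zero_rates_all_censored(self):
        tbl = pd.DataFrame({"age_lo": [0, 5], "age_hi": [5, 10], "rate_per_100k": [0.0, 0.0]})
        cohort = sample_cohort_from_curves(50, seed=0, incidence_table=tbl)
        assert cohort.df["censored"].all()
        assert (cohort.df["age"] == 10.0).all()

    def test_survival_to_zero_means_no_censoring(self):
        crv = pd.DataFrame({"age": [0, 20, 40, 60], "survival": [1.0, 0.7, 0.2, 0.0]})
        cohort = sample_cohort_from_curves(200, seed=1, survival_curve=crv)
        assert not cohort.df["censored"].any()
        assert (cohort.df["age"] <= 60.0).all()

    def test_seeded_reproducibility(self):
        tbl = pd.DataFrame({"age_lo": [0, 40], "age_hi": [40, 85], "rate_per_100k": [5.0, 50.0]})
        c1 = sample_cohort_from_curves(100, seed=2, incidence_table=tbl)
        c2 = sample_cohort_from_curves(100, seed=2, incidence_table=tbl)
        pd.testing.assert_frame_equal(c1.df, c2.df)

    def test_non_monotone_survival_rejected(self):
        crv = pd.DataFrame({"age": [0, 10, 20], "survival": [1.0, 0.5, 0.7]})
        with pytest.raises(ValueError, match="non-increasing"):
            sample_cohort_from_curves(10, survival_curve=crv)

    def test_negative_rate_rejected(self):
        tbl = pd.DataFrame({"age_lo": [0], "age_hi": [5], "rate_per_100k": [-1.0]})
        with pytest.raises(ValueError):
            sample_cohort_from_curves(10, incidence_table=tbl)

    def test_exactly_one_input(self):
        with pytest.raises(ValueError):
            sample_cohort_from_curves(10)

    def test_roundtrip_from_emulated_survival(self):
        # carriers drawn from the model-emulated curve reproduce its shape
        crv = synthetic.survival_curve_from_model(2, 0.2, 4, 0.16, n_mc=100_000, seed=3)
        cohort = sample_cohort_from_curves(3000, seed=4, survival_curve=crv)
        events = cohort.df.loc[~cohort.df["censored"], "age"]
        rng = np.random.default_rng(5)
        direct = rng.gamma(2, 1 / 0.2, 20_000) + rng.gamma(4, 1 / 0.16, 20_000)
        direct = direct[direct <= crv["age"].iloc[-1]]
        assert stats.ks_2samp(events, direct).pvalue > 0.001


class TestDirichletSplit:
    def test_sum_preserved_exactly(self, rng):
        y = np.array([50.0, 60.0, 70.0])
        z = np.column_stack([0.3 * y, 0.2 * y, 0.5 * y])
        for _ in range(200):
            z, _ = dirichlet_split_update(rng, y, z, [2.0, 1.0, 4.0], [0.2, 0.01, 0.16], kappa=10.0)
            np.testing.assert_allclose(z.sum(axis=1), y, rtol=1e-12)
            assert (z > 0).all()

    def test_uniform_split_oracle(self, rng):
        # equal exponential components: the long-run split fraction is uniform
        y = np.array([50.0])
        z = np.array([[25.0, 25.0]])
        fractions = []
        for i in range(20_000):
            z, _ = dirichlet_split_update(rng, y, z, [1.0, 1.0], [0.05, 0.05], kappa=5.0)
            if i >= 2000 and i % 5 == 0:
                fractions.append(z[0, 0] / 50.0)
        assert stats.kstest(fractions, "uniform").pvalue > 0.005

    def test_empty_input(self, rng):
        z, n_acc = dirichlet_split_update(rng, np.empty(0), np.empty((0, 2)), [1, 1], [1, 1], 10.0)
        assert n_acc == 0

    def test_bad_kappa(self, rng):
        with pytest.raises(ValueError):
            dirichlet_split_update(rng, np.array([1.0]), np.array([[0.5, 0.5]]), [1, 1], [1, 1], 0.0)


class TestCensoredRejection:
    def test_zero_censor_age_first_draw(self, rng):
        out = censored_rejection_update(rng, np.zeros(100), [2.0, 4.0], [0.2, 0.16])
        assert out.shape == (100, 2)
        assert (out.sum(axis=1) > 0).all()

    def test_sums_exceed_censor_age(self, rng):
        censor = np.full(10_000, 60.0)
        out = censored_rejection_update(rng, censor, [2.0, 4.0], [0.2, 0.16])
        assert (out.sum(axis=1) > 60.0).all()

    def test_matches_truncated_sum_oracle(self, rng):
        # two equal-rate exponential components: the sum is Gamma(2, b)
        # truncated below at c; inverse-CDF oracle
        b, c = 0.05, 60.0
        out = censored_rejection_update(rng, np.full(10_000, c), [1.0, 1.0], [b, b])
        sums = out.sum(axis=1)
        dist = stats.gamma(a=2, scale=1 / b)
        f_c = dist.cdf(c)

        def truncated_cdf(x):
            return (dist.cdf(x) - f_c) / (1 - f_c)

        assert stats.kstest(sums, truncated_cdf).pvalue > 0.005

    def test_attempt_cap_raises(self, rng):
        with pytest.raises(RuntimeError, match="pathological"):
            censored_rejection_update(
                rng, np.array([1e6]), [1.0, 1.0], [1.0, 1.0], max_attempts=5
            )


def _grid_posterior_mean_beta(prior, z, a_max=40.0, b_max=120.0, n_a=400, n_b=600):
    """Brute-force 2-D grid integral of the (shape, rate) posterior."""
    z = np.asarray(z, dtype=float)
    n = z.size
    sum_log_z = float(np.log(z).sum()) if n else 0.0
    sum_z = float(z.sum()) if n else 0.0
    a = np.linspace(1e-3, a_max, n_a)
    b = np.linspace(1e-3, b_max, n_b)
    A, B = np.meshgrid(a, b, indexing="ij")
    logd = (
        (A - 1.0) * (prior.log_p + sum_log_z)
        - B * (prior.q + sum_z)
        - (prior.r + n) * gammaln(A)
        + A * (prior.s + n) * np.log(B)
    )
    logd -= logd.max()
    w = np.exp(logd)
    return float((B * w).sum() / w.sum())


class TestShapeRateUpdate:
    def test_prior_only_matches_grid_oracle(self, rng):
        # a proper prior (p < 1 keeps the shape marginal integrable); no data
        prior = GammaPairPrior(log_p=np.log(0.5), q=1.0, r=1.0, s=1.0)
        a, b = 1.0, 1.0
        betas = []
        for i in range(60_000):
            a, b, _ = shape_rate_update(rng, np.empty(0), prior, gamma_scale=3.0, a=a, b=b)
            if i >= 5000:
                betas.append(b)
        oracle = _grid_posterior_mean_beta(prior, [])
        assert np.mean(betas) == pytest.approx(oracle, rel=0.05)

    def test_posterior_concentrates_with_data(self, rng):
        z = rng.gamma(2.0, 1 / 0.1, size=3000)
        a, b = 1.0, 1.0
        chain = []
        for i in range(4000):
            a, b, _ = shape_rate_update(rng, z, GammaPairPrior.uninformative(), 400.0, a, b)
            if i >= 2000:
                chain.append((a, b))
        a_mean, b_mean = np.mean(chain, axis=0)
        assert a_mean == pytest.approx(2.0, rel=0.05)
        assert b_mean == pytest.approx(0.1, rel=0.05)

    def test_huge_concentration_means_high_acceptance(self, rng):
        z = rng.gamma(2.0, 1 / 0.1, size=100)
        accepted = 0
        a, b = 2.0, 0.1
        for _ in range(200):
            a, b, ok = shape_rate_update(rng, z, GammaPairPrior.uninformative(), 1e8, a, b)
            accepted += ok
        assert accepted / 200 > 0.95

    def test_bad_gamma_scale(self, rng):
        with pytest.raises(ValueError):
            shape_rate_update(rng, np.array([1.0]), GammaPairPrior.uninformative(), 0.0, 1.0, 1.0)


class TestLambdaUpdate:
    def test_conjugate_arithmetic(self, rng):
        draws = np.array([lambda_update(rng, 3, 30.0) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(3.01 / 30.01, abs=4 * 0.0578 / np.sqrt(50_000))

    def test_no_data_returns_prior(self, rng):
        draws = np.array([lambda_update(rng, 0, 0.0) for _ in range(100_000)])
        # prior Gamma(0.01, 0.01): mean 1, heavy-tailed
        assert draws.mean() == pytest.approx(1.0, abs=0.15)

    def test_seeded_reproducibility(self):
        d1 = lambda_update(np.random.default_rng(7), 3, 30.0)
        d2 = lambda_update(np.random.default_rng(7), 3, 30.0)
        assert d1 == d2


@pytest.fixture(scope="module")
def small_cohort():
    return synthetic.simulate_incidence_cohort(
        nu=300, mu=2.1e-6, z1_shape=2, z1_rate=0.2, z3_shape=4, z3_rate=0.16,
        n_sporadic=150, n_inherited=80, seed=13,
    )


@pytest.fixture(scope="module")
def informative_priors():
    ages = np.random.default_rng(14).gamma(2.0, 1 / 0.2, size=20)
    return WaitingTimePriors(z1=GammaPairPrior.from_observed_ages(ages))


class TestRunGibbs:
    def test_deterministic(self, small_cohort, informative_priors):
        config = SamplerConfig(iterations=300, burn_in=100, thin=2, seed=21)
        d1 = run_gibbs(small_cohort, informative_priors, mu=2.1e-6, config=config)
        d2 = run_gibbs(small_cohort, informative_priors, mu=2.1e-6, config=config)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)

    def test_draw_count_and_nu(self, small_cohort, informative_priors):
        config = SamplerConfig(iterations=400, burn_in=100, thin=3, seed=22)
        d = run_gibbs(small_cohort, informative_priors, mu=2.1e-6, config=config)
        assert len(d.draws) == int(np.ceil((400 - 100) / 3))
        assert (d.draws["nu"] > 0).all()
        np.testing.assert_allclose(d.draws["nu"], d.draws["lam"] / 2.1e-6)

    def test_inherited_only_lambda_follows_prior(self, informative_priors):
        cohort = synthetic.simulate_incidence_cohort(
            nu=300, mu=2.1e-6, z1_shape=2, z1_rate=0.2, z3_shape=4, z3_rate=0.16,
            n_sporadic=0, n_inherited=40, seed=23,
        )
        config = SamplerConfig(iterations=12_000, burn_in=2000, thin=1, seed=24)
        d = run_gibbs(cohort, informative_priors, mu=2.1e-6, config=config)
        # no z2 data: lambda draws are prior Gamma(0.01, 0.01) draws
        assert d.draws["lam"].mean() == pytest.approx(1.0, abs=0.5)

    def test_empty_cohort_rejected(self, informative_priors):
        empty = synthetic.IncidenceCohort(pd.DataFrame(columns=["group", "age", "censored"]))
        with pytest.raises(ValueError):
            run_gibbs(empty, informative_priors, mu=2.1e-6, config=SamplerConfig(iterations=10, burn_in=1))

    def test_lambda_marginal_matches_integration_oracle(self):
        # 3 uncensored sporadic individuals, (shape, rate) pairs held fixed:
        # compare the sampler's lambda posterior mean with a brute-force
        # numerical-integration oracle
        a1, b1, a3, b3 = 2.0, 0.2, 4.0, 0.16
        lam_prior = (2.0, 20.0)
        ys = np.array([45.0, 60.0, 70.0])
        cohort = synthetic.IncidenceCohort(
            pd.DataFrame({"group": "sporadic", "age": ys, "censored": False})
        )
        priors = WaitingTimePriors(lambda_shape=lam_prior[0], lambda_rate=lam_prior[1])
        config = SamplerConfig(
            iterations=40_000, burn_in=5000, thin=2, kappa=5.0, seed=31, update_shape_rate=False
        )
        # inject the fixed (shape, rate) values as the sampler's start point
        import clonaltiming.incidence as inc

        original = inc._initial_state

        def fixed_init(rng, cohort_, priors_):
            st = original(rng, cohort_, priors_)
            st["a1"], st["b1"], st["a3"], st["b3"] = a1, b1, a3, b3
            return st

        inc._initial_state = fixed_init
        try:
            draws = run_gibbs(cohort, priors, mu=2.1e-6, config=config)
        finally:
            inc._initial_state = original
        sampler_mean = draws.draws["lam"].mean()

        # oracle: m_i(lam) = int conv13(s) lam exp(-lam (y_i - s)) ds
        ds = 0.01
        s = np.arange(ds, 120.0, ds)
        f1 = stats.gamma(a=a1, scale=1 / b1).pdf(s)
        f3 = stats.gamma(a=a3, scale=1 / b3).pdf(s)
        conv13 = np.convolve(f1, f3)[: len(s)] * ds
        lam_grid = np.linspace(1e-4, 3.0, 4000)
        log_post = stats.gamma(a=lam_prior[0], scale=1 / lam_prior[1]).logpdf(lam_grid)
        for y in ys:
            mask = s < y
            m = np.array(
                [np.sum(conv13[mask] * lam * np.exp(-lam * (y - s[mask]))) * ds for lam in lam_grid]
            )
            log_post += np.log(np.maximum(m, 1e-300))
        w = np.exp(log_post - log_post.max())
        oracle_mean = float(np.sum(lam_grid * w) / np.sum(w))
        assert sampler_mean == pytest.approx(oracle_mean, rel=0.05)


@pytest.fixture(scope="module")
def fitted_draws(small_cohort, informative_priors):
    config = SamplerConfig(iterations=2000, burn_in=500, thin=3, seed=41)
    return run_gibbs(small_cohort, informative_priors, mu=2.1e-6, config=config)


class TestIntervention:
    def test_z2_mean_scales_inversely_with_rho(self, fitted_draws):
        _, z2_full = simulate_intervention(fitted_draws, rho=1.0, n_per_draw=400, seed=42)
        _, z2_half = simulate_intervention(fitted_draws, rho=0.5, n_per_draw=400, seed=42)
        assert z2_half.mean() / z2_full.mean() == pytest.approx(2.0, rel=0.1)

    def test_cumulative_incidence_monotone_in_rho(self, fitted_draws):
        ages = np.arange(0, 91, 5.0)
        curves = {
            rho: intervention_curves(fitted_draws, rho, ages=ages, n_per_draw=300, seed=43)
            for rho in (1.0, 0.75, 0.5, 0.25)
        }
        for hi, lo in [(1.0, 0.75), (0.75, 0.5), (0.5, 0.25)]:
            diff = curves[hi]["cumulative_incidence"] - curves[lo]["cumulative_incidence"]
            assert (diff >= -0.02).all()  # pointwise, up to Monte-Carlo jitter
        assert curves[1.0]["cumulative_incidence"].iloc[-1] > curves[0.25]["cumulative_incidence"].iloc[-1]

    def test_identity_intervention_matches_model(self, fitted_draws):
        onset, _ = simulate_intervention(fitted_draws, rho=1.0, n_per_draw=200, seed=44)
        med = fitted_draws.draws.median()
        rng = np.random.default_rng(45)
        model_onset = (
            rng.gamma(med["a1"], 1 / med["b1"], 20_000)
            + rng.exponential(1 / med["lam"], 20_000)
            + rng.gamma(med["a3"], 1 / med["b3"], 20_000)
        )
        # same family, parameter uncertainty only: medians should be close
        assert np.median(onset) == pytest.approx(np.median(model_onset), rel=0.15)

    def test_bad_rho(self, fitted_draws):
        for rho in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                simulate_intervention(fitted_draws, rho=rho)


class TestConfig:
    def test_burn_in_bound(self):
        with pytest.raises(ValueError):
            SamplerConfig(iterations=100, burn_in=100)

    def test_positive_scales(self):
        with pytest.raises(ValueError):
            SamplerConfig(iterations=100, burn_in=10, kappa=-1.0)
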