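import math

import numpy as np
import pytest
import scipy.stats as st
from scipy.integrate import quad

from hyphatrack.dist_fitting import (
    DistributionSpec,
    FitInputError,
    FitResult,
    default_pool,
    fit_mle,
    information_criteria,
    pdf,
    rank_models,
)


def truncated_draws(dist, n, rng, lo=0.0, hi=100.0):
    """Inverse-CDF draws from a scipy distribution truncated to (lo, hi]."""
    return dist.ppf(rng.uniform(dist.cdf(lo), dist.cdf(hi), n))


def mixture_draws(dist, w, n, rng, hi=100.0):
    comp = rng.random(n) < w
    return np.where(comp, truncated_draws(dist, n, rng, hi=hi), rng.uniform(0, hi, n))


class TestSpecAndPdf:
    def test_uniform_density_is_flat(self):
        fit = FitResult(DistributionSpec("uniform"), {}, 0.0, 100)
        assert pdf(fit, 50.0) == pytest.approx(0.01)
        assert pdf(fit, -1.0) == 0.0
        assert pdf(fit, 101.0) == 0.0

    def test_degenerate_mixture_weight_zero_is_uniform(self):
        fit = FitResult(DistributionSpec("lognormal", mixture=True),
                        {"mu": 0.5, "sigma": 1.0, "w": 0.0}, 0.0, 100)
        x = np.linspace(0.5, 99.5, 37)
        np.testing.assert_allclose(fit.pdf(x), 0.01, rtol=1e-12)

    @pytest.mark.parametrize("spec,params", [
        (DistributionSpec("cauchy"), {"x0": 2.0, "gamma": 1.0}),
        (DistributionSpec("lognormal"), {"mu": 0.6, "sigma": 0.8}),
        (DistributionSpec("normal", mixture=True), {"mu": 3.0, "sigma": 2.0, "w": 0.6}),
        (DistributionSpec("weibull", support=(60.0, 100.0)),
         {"shape": 1.4, "scale": 30.0}),
    ])
    def test_pdf_integrates_to_one_over_support(self, spec, params):
        fit = FitResult(spec, params, 0.0, 100)
        lo, hi = spec.support
        total, _ = quad(lambda v: float(fit.pdf(v)), lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_matches_pdf_quadrature(self):
        fit = FitResult(DistributionSpec("cauchy", mixture=True),
                        {"x0": 2.0, "gamma": 1.5, "w": 0.7}, 0.0, 100)
        for x in (0.5, 2.0, 10.0, 80.0):
            num, _ = quad(lambda v: float(fit.pdf(v)), 0, x, limit=200)
            assert float(fit.cdf(x)) == pytest.approx(num, abs=1e-7)

    def test_sample_agrees_with_cdf(self):
        fit = FitResult(DistributionSpec("lognormal", mixture=True),
                        {"mu": 0.7, "sigma": 0.6, "w": 0.7}, 0.0, 5000)
        draws = fit.sample(5000, seed=4)
        assert ((draws > 0) & (draws <= 100)).all()
        d, p = st.kstest(draws, lambda v: np.asarray(fit.cdf(v)))
        assert p > 0.01


class TestFitMLE:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(11)
        x = truncated_draws(st.lognorm(s=0.6, scale=math.exp(0.7)), 5000, rng)
        fit = fit_mle(x, DistributionSpec("lognormal"), seed=0)
        assert fit.converged
        assert fit.params["mu"] == pytest.approx(0.7, abs=0.03)
        assert fit.params["sigma"] == pytest.approx(0.6, abs=0.02)

    def test_mixture_weight_recovery(self):
        rng = np.random.default_rng(12)
        x = mixture_draws(st.lognorm(s=0.6, scale=math.exp(0.7)), 0.7, 5000, rng)
        fit = fit_mle(x, DistributionSpec("lognormal", mixture=True), seed=0)
        assert fit.params["w"] == pytest.approx(0.7, abs=0.05)

    def test_constant_sample_under_uniform_has_exact_loglik(self):
        x = np.full(50, 42.0)
        fit = fit_mle(x, DistributionSpec("uniform"), seed=0)
        assert fit.log_likelihood == pytest.approx(50 * math.log(0.01))

    def test_samples_outside_support_rejected(self):
        with pytest.raises(FitInputError):
            fit_mle(np.linspace(1, 150, 100), DistributionSpec("lognormal"), seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FitInputError):
            fit_mle(np.linspace(1, 9, 5), DistributionSpec("lognormal"), seed=0)

    def test_mixture_loglik_dominates_nested_single(self):
        rng = np.random.default_rng(8)
        x = truncated_draws(st.gamma(a=2.0, scale=3.0), 800, rng)
        single = fit_mle(x, DistributionSpec("gamma"), seed=1)
        mixed = fit_mle(x, DistributionSpec("gamma", mixture=True), seed=1)
        assert mixed.log_likelihood >= single.log_likelihood - 1e-6

    def test_loglik_at_least_truth_on_own_family(self):
        rng = np.random.default_rng(5)
        spec = DistributionSpec("cauchy")
        true_params = np.array([3.0, 1.5])
        d = st.cauchy(loc=3.0, scale=1.5)
        x = truncated_draws(d, 2000, rng)
        fit = fit_mle(x, spec, seed=2)
        z = d.cdf(100) - d.cdf(0)
        ll_truth = float(np.sum(d.logpdf(x) - math.log(z)))
        assert fit.log_likelihood >= ll_truth - 1e-6

    def test_grid_search_oracle_agreement(self):
        """MLE log-likelihood matches a dense 2-parameter grid maximum."""
        rng = np.random.default_rng(42)
        x = truncated_draws(st.lognorm(s=0.5, scale=math.exp(1.0)), 200, rng)
        fit = fit_mle(x, DistributionSpec("lognormal"), seed=3)
        mus = np.linspace(0.6, 1.4, 120)
        sigmas = np.linspace(0.3, 0.8, 120)
        lx = np.log(x)
        best = -np.inf
        for mu in mus:
            for sg in sigmas:
                z = st.norm.cdf((math.log(100) - mu) / sg)
                ll = np.sum(st.norm.logpdf(lx, mu, sg) - lx - math.log(z))
                best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-9
        assert fit.log_likelihood == pytest.approx(best, abs=0.1)

    def test_boundary_weight_is_flagged(self):
        rng = np.random.default_rng(6)
        x = truncated_draws(st.lognorm(s=0.5, scale=math.exp(0.8)), 1500, rng)
        fit = fit_mle(x, DistributionSpec("lognormal", mixture=True), seed=0)
        assert fit.params["w"] > 0.99
        assert fit.boundary


class TestInformationCriteria:
    def test_worked_arithmetic_example(self):
        fit = FitResult(DistributionSpec("lognormal"), {"mu": 0, "sigma": 1}, -100.0, 100)
        ics = information_criteria(fit)
        assert ics.aic == pytest.approx(204.0)
        assert ics.bic == pytest.approx(2 * math.log(100) + 200)
        assert ics.hqc == pytest.approx(4 * math.log(math.log(100)) + 200)

    def test_zero_parameter_family(self):
        fit = FitResult(DistributionSpec("uniform"), {}, -55.0, 100)
        assert information_criteria(fit).aic == pytest.approx(110.0)

    def test_nested_pair_aic_identity(self):
        rng = np.random.default_rng(13)
        x = truncated_draws(st.lognorm(s=0.6, scale=math.exp(0.7)), 500, rng)
        single = fit_mle(x, DistributionSpec("lognormal"), seed=0)
        mixed = fit_mle(x, DistributionSpec("lognormal", mixture=True), seed=0)
        d_aic = information_criteria(mixed).aic - information_criteria(single).aic
        d_ll = mixed.log_likelihood - single.log_likelihood
        assert d_aic == pytest.approx(2 * 1 - 2 * d_ll, abs=1e-9)

    def test_tiny_n_rejected_for_hqc(self):
        fit = FitResult(DistributionSpec("uniform"), {}, -1.0, 2)
        with pytest.raises(ValueError, match="n > e"):
            information_criteria(fit)


class TestRankModels:
    def test_single_spec_pool(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 200)
        ranking = rank_models(x, pool=[DistributionSpec("uniform")], seed=0)
        assert len(ranking.fits) == 1
        assert ranking.best.spec.family == "uniform"

    def test_uniform_data_selects_uniform(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, 3000)
        ranking = rank_models(x, seed=0, n_restarts=6)
        assert ranking.best.spec.name == "uniform"

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        x = mixture_draws(st.lognorm(s=0.7, scale=math.exp(0.6)), 0.65, 800, rng)
        a = rank_models(x, seed=5, n_restarts=4)
        b = rank_models(x[::-1], seed=5, n_restarts=4)
        assert [f.spec.name for f in a.fits] == [f.spec.name for f in b.fits]
        assert a.best.log_likelihood == pytest.approx(b.best.log_likelihood, abs=1e-9)

    def test_default_pool_composition(self):
        pool = default_pool()
        names = {s.name for s in pool}
        assert len(pool) == 13
        assert {"lognormal+uniform", "cauchy+uniform", "uniform"} <= names

    def test_ranking_table_has_all_criteria(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 300)
        frame = rank_models(x, seed=0, n_restarts=3).to_frame()
        assert {"rank", "family", "logL", "AIC", "BIC", "HQC"} <= set(frame.columns)
        assert len(frame) <= 10
        assert frame["BIC"].is_monotonic_increasing
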