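import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_posterior, short_chain

from asvglmm import (
    LongObservations,
    MCMCConfig,
    PosteriorSamples,
    PriorSpec,
    diagnostics,
    fit_glmm,
    predicted_zero_ratio,
)
from asvglmm.model_spec import GAUSSIAN, POISSON, ModelSpec, RandomTerm


def _intercept_obs(y):
    n = len(y)
    return LongObservations(pd.DataFrame({
        "asv_id": "A1", "sample_id": [f"S{i}" for i in range(n)],
        "host_id": "H1", "group": "G1", "count": y,
    }))


def _intercept_spec(residual=False):
    return ModelSpec(
        family=POISSON, fixed_group=None, random_terms=[],
        residual_term=RandomTerm("res", ("asv_id", "sample_id")) if residual else None,
    )


class TestFitGlmm:
    def test_intercept_only_matches_gamma_poisson_conjugacy(self):
        # 200 rows of count 5; the row-level term's variance is pinned to a
        # negligible value, so the model collapses to a Poisson intercept.
        # Under the (effectively flat) intercept prior the posterior of
        # exp(beta0) is Gamma(sum y, n): mean 5, sd sqrt(1000)/200.
        y = np.full(200, 5)
        obs = _intercept_obs(y)
        spec = _intercept_spec(residual=True)
        prior = PriorSpec(term_V={"res": 1e-8}, term_nu={"res": 1e8}, expand=False)
        ps = fit_glmm(obs, spec, prior=prior,
                      cfg=MCMCConfig(n_iterations=8000, burn_in=2000, thin=3,
                                     n_chains=1, seed=11))
        lam_draws = np.exp(ps.flat_fixed("intercept"))
        g_mean, g_sd = 1000 / 200, np.sqrt(1000) / 200
        assert abs(lam_draws.mean() - g_mean) < 3 * g_sd
        assert lam_draws.std() == pytest.approx(g_sd, rel=0.25)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        obs = _intercept_obs(rng.poisson(4.0, 60))
        spec = _intercept_spec(residual=True)
        cfg = MCMCConfig(n_iterations=400, burn_in=100, thin=2, n_chains=2, seed=5)
        a = fit_glmm(obs, spec, cfg=cfg)
        b = fit_glmm(obs, spec, cfg=cfg)
        np.testing.assert_array_equal(a.fixed["intercept"], b.fixed["intercept"])
        np.testing.assert_array_equal(a.variances["res"], b.variances["res"])
        c = fit_glmm(obs, spec, cfg=MCMCConfig(n_iterations=400, burn_in=100,
                                               thin=2, n_chains=2, seed=6))
        assert not np.array_equal(a.fixed["intercept"], c.fixed["intercept"])

    def test_prior_recovery_without_likelihood(self):
        # likelihood switched off: variance draws must reproduce the
        # inverse-gamma prior IG(nu/2, nu V/2) = IG(3, 3)
        obs = _intercept_obs(np.zeros(30, dtype=int))
        spec = ModelSpec(family=POISSON, fixed_group=None,
                         random_terms=[RandomTerm("res", ("asv_id", "sample_id"))],
                         residual_term=None)
        ps = fit_glmm(obs, spec, prior=PriorSpec(V=1.0, nu=6.0, expand=False),
                      cfg=MCMCConfig(n_iterations=21000, burn_in=1000, thin=5,
                                     n_chains=1, seed=3),
                      prior_only=True)
        draws = ps.flat_variance("res")
        ref = stats.invgamma(a=3.0, scale=3.0)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(draws, q) == pytest.approx(ref.ppf(q), rel=0.10)

    def test_poisson_rejects_non_integer_response(self):
        obs = _intercept_obs(np.zeros(20, dtype=int))
        obs.data["count"] = obs.data["count"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            fit_glmm(obs, _intercept_spec(), cfg=short_chain(1))

    def test_gaussian_family_fits_real_response(self):
        rng = np.random.default_rng(4)
        n = 120
        df = pd.DataFrame({
            "asv_id": np.repeat([f"A{i}" for i in range(6)], 20),
            "sample_id": [f"S{i}" for i in range(n)],
            "host_id": "H1", "group": "G1",
            "value": rng.normal(2.0, 1.0, n),
        })
        obs = LongObservations(df, response="value")
        spec = ModelSpec(family=GAUSSIAN, fixed_group=None,
                         random_terms=[RandomTerm("asv", ("asv_id",))],
                         residual_term=None)
        ps = fit_glmm(obs, spec, cfg=short_chain(2, 2000, 500, 3))
        assert abs(ps.flat_fixed("intercept").mean() - 2.0) < 0.5
        assert "residual" in ps.variances


class TestDiagnostics:
    @staticmethod
    def _ps_with(draws2d):
        return make_posterior(variances={"term": draws2d},
                              fixed={"intercept": np.zeros_like(np.atleast_2d(draws2d))})

    def test_white_noise_ess_near_n(self):
        rng = np.random.default_rng(0)
        n = 2000
        ps = self._ps_with(np.abs(rng.normal(size=(1, n))) + 0.1)
        d = diagnostics(ps)
        assert d.ess["sigma2:term"] == pytest.approx(n, rel=0.2)

    def test_ar1_ess_far_below_n(self):
        rng = np.random.default_rng(1)
        n, rho = 2000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.normal()
        ps = self._ps_with(np.exp(x)[None])  # keep positivity for a variance
        d = diagnostics(ps)
        # analytic ESS of AR(1) at rho=0.9 is n/19; allow sampling slack
        assert d.ess["sigma2:term"] < 0.2 * n
        assert d.lag1_autocorr["sigma2:term"] > 0.7

    def test_constant_draws_flagged_not_crashing(self):
        ps = self._ps_with(np.ones((1, 500)))
        d = diagnostics(ps)
        assert "sigma2:term" in d.flagged
        assert np.isnan(d.lag1_autocorr["sigma2:term"])

    def test_too_few_draws_rejected(self):
        ps = self._ps_with(np.ones((1, 20)))
        with pytest.raises(ValueError, match="50"):
            diagnostics(ps)

    def test_rhat_reported_for_multiple_chains(self):
        rng = np.random.default_rng(2)
        ps = self._ps_with(np.abs(rng.normal(size=(2, 400))) + 0.1)
        d = diagnostics(ps)
        assert d.rhat is not None
        assert d.rhat["sigma2:term"] == pytest.approx(1.0, abs=0.05)


class TestZeroRatio:
    def test_all_zero_counts_ratio_one(self):
        obs = _intercept_obs(np.zeros(60, dtype=int))
        ps = fit_glmm(obs, _intercept_spec(), cfg=short_chain(7, 2000, 500, 3))
        assert predicted_zero_ratio(ps, obs) == pytest.approx(1.0, abs=0.02)

    def test_no_observed_zeros_warns_and_returns_zero_ish(self):
        rng = np.random.default_rng(8)
        obs = _intercept_obs(rng.poisson(50.0, 60) + 1)
        ps = fit_glmm(obs, _intercept_spec(), cfg=short_chain(8, 1500, 500, 2))
        with pytest.warns(RuntimeWarning, match="no zeros"):
            ratio = predicted_zero_ratio(ps, obs)
        assert ratio == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_family_rejected(self):
        ps = make_posterior(variances={"a": np.ones(60), "residual": np.ones(60)},
                            family=GAUSSIAN)
        with pytest.raises(ValueError, match="Poisson"):
            predicted_zero_ratio(ps, _intercept_obs(np.zeros(3, dtype=int)))


class TestPosteriorInterchange:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        obs = _intercept_obs(rng.poisson(4.0, 40))
        spec = ModelSpec(family=POISSON, fixed_group=None,
                         random_terms=[RandomTerm("asv", ("asv_id",))],
                         residual_term=RandomTerm("res", ("asv_id", "sample_id")))
        ps = fit_glmm(obs, spec, cfg=MCMCConfig(n_iterations=300, burn_in=100,
                                                thin=2, n_chains=2, seed=1))
        p = tmp_path / "posterior.tsv"
        ps.to_tsv(p, include_terms=["asv"])
        back = PosteriorSamples.from_tsv(p, ps.meta_dict())
        np.testing.assert_allclose(back.fixed["intercept"], ps.fixed["intercept"])
        np.testing.assert_allclose(back.variances["res"], ps.variances["res"])
        np.testing.assert_allclose(back.random["asv"], ps.random["asv"])
        assert back.term_labels["asv"] == ps.term_labels["asv"]

    def test_summary_reports_moments(self):
        ps = make_posterior(variances={"a": np.linspace(1, 2, 100)},
                            fixed={"intercept": np.zeros(100)})
        s = ps.summary()
        assert s["sigma2:a"]["mean"] == pytest.approx(1.5)
        assert s["beta:intercept"]["sd"] == 0.0
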