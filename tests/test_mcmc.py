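"""Posterior machinery: priors, sampler correctness, convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from otolife import (
    GrowthParams,
    McmcConfig,
    convergence_diagnostics,
    default_priors,
    log_prior,
    run_mcmc,
    simulate_catch,
)
from otolife.mcmc import (
    McmcResult,
    PriorSpec,
    gelman_rubin_psrf,
    geweke_z,
    heidelberger_welch_stationary,
)


class TestLogPrior:
    def test_density_at_medians(self):
        pri = default_priors()
        expected = sum(
            -np.log(sd * np.sqrt(2 * np.pi)) for sd in pri.sd_vector()
        )
        assert log_prior(pri.mu_vector(), pri) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_normal_logpdf_sum(self, table1_params):
        pri = default_priors()
        x = np.log(table1_params.to_array())
        expected = stats.norm.logpdf(x, pri.mu_vector(), pri.sd_vector()).sum()
        assert log_prior(x, pri) == pytest.approx(float(expected), abs=1e-10)
        assert log_prior(table1_params, pri) == pytest.approx(float(expected), abs=1e-10)

    def test_nonpositive_parameter_rejected(self):
        pri = default_priors()
        x = pri.mu_vector()
        x[0] = np.nan
        assert log_prior(x, pri) == -np.inf

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(medians={"linf": 1000.0}, log_sds={"linf": 1.0})
        pri = default_priors()
        with pytest.raises(ValueError):
            PriorSpec(medians={**pri.medians, "k": -1}, log_sds=pri.log_sds)


class TestSampler:
    def test_rejects_tiny_datasets(self):
        with pytest.raises(ValueError):
            run_mcmc(np.array([[5.0, 800.0]] * 10))

    def test_prior_recovery_with_constant_likelihood(self):
        """With no data the sampler must reproduce the prior: medians,
        log-scale SDs, and the full marginal shape (KS on thinned draws)."""
        pri = default_priors()
        res = run_mcmc(
            None, pri,
            McmcConfig(n_chains=6, burn_in=2000, n_samples=200_000, seed=11),
        )
        med = res.posterior_median()
        log_sd = res.posterior_log_sd()
        for name in res.param_names:
            assert med[name] == pytest.approx(pri.medians[name], rel=0.05)
            assert log_sd[name] == pytest.approx(pri.log_sds[name], rel=0.10)
        z = (res.pooled_ - pri.mu_vector()) / pri.sd_vector()
        for j in range(z.shape[1]):
            assert stats.kstest(z[::999, j], "norm").pvalue > 0.01

    def test_seed_determinism_and_chain_distinctness(self):
        cfg = McmcConfig(n_chains=2, burn_in=200, n_samples=500, seed=5)
        a = run_mcmc(None, default_priors(), cfg)
        b = run_mcmc(None, default_priors(), cfg)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(a.draws[0], a.draws[1])

    def test_short_data_fit_runs_and_summarises(self, table1_params):
        obs = simulate_catch(table1_params, 200, seed=2)
        res = run_mcmc(
            obs, default_priors(),
            McmcConfig(n_chains=2, burn_in=2500, n_samples=600, seed=9),
        )
        assert res.draws.shape == (2, 600, 8)
        assert np.all(np.isfinite(res.draws))
        table = res.summary_table()
        assert list(table["parameter"]) == list(res.param_names)
        assert (table["posterior_mean"] > 0).all()
        assert 0.05 < res.acceptance.mean() < 0.7


class TestDiagnostics:
    def _make_result(self, chains):
        chains = np.asarray(chains)
        draws = np.repeat(chains[:, :, None], 8, axis=2)
        return McmcResult(
            draws=draws,
            acceptance=np.full(chains.shape[0], 0.3),
            scales=np.ones((chains.shape[0], 8)),
            config=McmcConfig(n_chains=chains.shape[0], burn_in=0,
                              n_samples=chains.shape[1]),
        )

    def test_iid_chains_pass_and_match_arviz_psrf(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(0, 1, (4, 2000))
        report = convergence_diagnostics(self._make_result(chains))
        assert report.passed
        assert report.psrf["linf"] < 1.05
        arviz = pytest.importorskip("arviz")
        ours = gelman_rubin_psrf(chains)
        theirs = float(arviz.rhat(chains[None].transpose(1, 2, 0)[..., 0]).values) \
            if hasattr(arviz.rhat(chains), "values") else float(arviz.rhat(chains))
        assert abs(ours - theirs) < 0.05

    def test_offset_chains_fail_psrf(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (4, 2000))
        chains[0] += 5.0  # five-SD displaced chain
        report = convergence_diagnostics(self._make_result(chains))
        assert report.psrf["linf"] > 1.1
        assert not report.passed
        assert report.failures()

    def test_trending_chain_fails_heidelberger_welch(self):
        rng = np.random.default_rng(2)
        trend = np.linspace(0, 6, 2000) + rng.normal(0, 1, 2000)
        assert not heidelberger_welch_stationary(trend)
        flat = rng.normal(0, 1, 2000)
        assert heidelberger_welch_stationary(flat)
        chains = np.vstack([trend, flat, flat + rng.normal(0, 1, 2000) * 0.0 , flat])
        report = convergence_diagnostics(self._make_result(chains))
        assert not report.passed

    def test_geweke_detects_mean_drift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 5000)
        assert abs(geweke_z(x)) < 3
        drift = np.concatenate([rng.normal(3, 1, 500), rng.normal(0, 1, 4500)])
        assert abs(geweke_z(drift)) > 2

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(4)
        res = self._make_result(rng.normal(0, 1, (1, 500)))
        with pytest.raises(ValueError):
            convergence_diagnostics(res)
        with pytest.raises(ValueError):
            gelman_rubin_psrf(rng.normal(0, 1, (1, 500)))
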