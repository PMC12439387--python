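"""Sampler correctness, posterior summaries and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

from wingmorph._gibbs import pg_draw_many
from wingmorph.animal_model import (
    MCMCConfig,
    ModelSpec,
    PosteriorSamples,
    PriorSpec,
    convergence_diagnostics,
    fit_animal_model,
    fit_logit_liability,
    hpd_interval,
    posterior_summary,
)


class TestPolyaGamma:
    """The PG(1, z) auxiliary sampler is exact (Devroye rejection)."""

    @pytest.mark.parametrize("z", [0.0, 0.8, 2.5, 7.0])
    def test_mean_matches_tanh_formula(self, z):
        draws = pg_draw_many(np.full(120_000, z), 42)
        mean_true = 0.25 if z == 0 else np.tanh(z / 2) / (2 * z)
        assert draws.mean() == pytest.approx(mean_true, rel=0.01)

    @pytest.mark.parametrize("z, t", [(0.0, 2.0), (1.5, 0.5), (4.0, 8.0)])
    def test_laplace_transform(self, z, t):
        """E[exp(-t w)] = cosh(z/2)/cosh(sqrt(t/2 + z^2/4))."""
        draws = pg_draw_many(np.full(120_000, z), 7)
        emp = np.exp(-t * draws).mean()
        theo = np.cosh(z / 2) / np.cosh(np.sqrt(t / 2 + z * z / 4))
        assert emp == pytest.approx(theo, abs=0.003)


class TestPosteriorSummary:
    def _wrap(self, arr):
        return PosteriorSamples(draws={"theta": np.atleast_2d(arr)})

    def test_degenerate_distribution(self):
        s = self._wrap(np.full(500, 5.0))
        tab = posterior_summary(s)
        row = tab.loc["theta"]
        assert row["median"] == 5.0
        assert row["sd"] == 0.0
        assert (row["hpd_low"], row["hpd_high"]) == (5.0, 5.0)

    def test_normal_hpd_endpoints(self):
        rng = np.random.default_rng(1)
        s = self._wrap(rng.standard_normal(100_000))
        row = posterior_summary(s).loc["theta"]
        assert row["hpd_low"] == pytest.approx(-1.96, abs=0.05)
        assert row["hpd_high"] == pytest.approx(1.96, abs=0.05)

    def test_uniform_order_statistic_median(self):
        s = self._wrap(np.arange(1.0, 101.0))
        assert posterior_summary(s).loc["theta", "median"] == 50.5

    def test_empty_and_short_samples_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(self._wrap(np.arange(10.0)))

    def test_hpd_is_shortest_interval(self):
        # right-skewed draws: HPD must be shorter than the equal-tailed interval
        rng = np.random.default_rng(2)
        draws = rng.gamma(2.0, 1.0, 50_000)
        lo, hi = hpd_interval(draws)
        q = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < q[1] - q[0]
        inside = ((draws >= lo) & (draws <= hi)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)


class TestConvergenceDiagnostics:
    def _wrap(self, chains):
        return PosteriorSamples(draws={"theta": np.asarray(chains)})

    def test_white_noise_chains_converged(self):
        rng = np.random.default_rng(0)
        s = self._wrap(rng.standard_normal((2, 5000)))
        row = convergence_diagnostics(s).loc["theta"]
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)
        assert row["converged"]

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack(
            [rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)]
        )
        row = convergence_diagnostics(self._wrap(chains)).loc["theta"]
        assert row["rhat"] > 1.5
        assert not row["converged"]

    def test_ar1_chain_has_deflated_ess(self):
        rng = np.random.default_rng(3)
        n, phi = 20_000, 0.95
        eps = rng.standard_normal((2, n))
        x = np.zeros((2, n))
        for t in range(1, n):
            x[:, t] = phi * x[:, t - 1] + eps[:, t]
        row = convergence_diagnostics(self._wrap(x)).loc["theta"]
        assert row["ess"] < 0.2 * 2 * n

    def test_single_chain_rhat_undefined(self):
        rng = np.random.default_rng(1)
        s = self._wrap(rng.standard_normal((1, 3000)))
        with pytest.warns(UserWarning, match="single chain"):
            row = convergence_diagnostics(s).loc["theta"]
        assert np.isnan(row["rhat"])


class TestFitBasics:
    def test_null_data_gives_small_variances_and_slope(self):
        """Data with no genetic, cage or density effects: posterior medians
        of V_A and beta stay near zero (checked across seeded replicates)."""
        from wingmorph.pedigree import relatedness_matrix
        from wingmorph.simulate import (
            SimulationConfig, pedigree_from_data, simulate_dataset,
        )

        hits = 0
        reps = 6
        for rep in range(reps):
            cfg = SimulationConfig(
                n_sires=10, seed=9100 + rep,
                alpha=0.0, beta=0.0, V_C=0.0, V_A_I=0.0, V_A_S=0.0, C_A_IS=0.0,
            )
            data = simulate_dataset(cfg)
            ped = pedigree_from_data(data)
            ids = data.loc[data["y"].notna(), "id"].astype(str).tolist()
            A = relatedness_matrix(ped, subset=ids)
            s = fit_animal_model(
                data, A, ModelSpec(random_slope=False),
                MCMCConfig(n_chains=2, warmup=400, sampling_iterations=800,
                           thin=2, seed=rep),
            )
            ok_va = np.median(s.pooled("V_A")) < 0.3
            ok_beta = abs(np.median(s.pooled("beta"))) < 0.2
            hits += ok_va and ok_beta
        assert hits >= reps - 1

    def test_variance_draws_nonnegative_and_cov_bounded(self, medium_dataset):
        data, ped, A, cfg = medium_dataset
        s = fit_animal_model(
            data, A, ModelSpec(random_slope=True),
            MCMCConfig(n_chains=2, warmup=300, sampling_iterations=600,
                       thin=2, seed=5),
        )
        for name in ("V_C", "V_A_I", "V_A_S"):
            assert (s.pooled(name) >= 0).all()
        corr = s.pooled("C_A_IS") / np.sqrt(
            s.pooled("V_A_I") * s.pooled("V_A_S")
        )
        assert (np.abs(corr) <= 1.0 + 1e-9).all()

    def test_exchangeability_under_row_permutation(self, small_dataset):
        """Permuting individuals (with matched A permutation) leaves
        posterior summaries invariant within Monte Carlo error."""
        data, ped, A, cfg = small_dataset
        mcmc = MCMCConfig(n_chains=2, warmup=400, sampling_iterations=1200,
                          thin=2, seed=3)
        s1 = fit_animal_model(data, A, ModelSpec(random_slope=False), mcmc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data))
        s2 = fit_animal_model(
            data.iloc[perm].reset_index(drop=True), A,
            ModelSpec(random_slope=False), mcmc,
        )
        for name in ("alpha", "beta"):
            assert np.median(s1.pooled(name)) == pytest.approx(
                np.median(s2.pooled(name)), abs=0.12
            )

    def test_slope_model_nests_basic_model(self, small_dataset):
        """With the slope variance pinned to zero the random-slope code path
        reproduces the basic model's posterior (KS distance < 0.1)."""
        from scipy.stats import ks_2samp

        data, ped, A, cfg = small_dataset
        df = data.loc[data["y"].notna()]
        y = df["y"].to_numpy(float)
        x = df["nymphal_density"].to_numpy(float) - 6.5
        X = np.column_stack([np.ones(len(y)), x])
        Asub = A.reorder(df["id"].astype(str).tolist()).A
        mcmc = MCMCConfig(n_chains=2, warmup=500, sampling_iterations=9000,
                          thin=6, seed=11)
        basic = fit_logit_liability(
            y, X, ["alpha", "beta"], df["cage_id"].to_numpy(), Asub,
            slope_covariate=None, mcmc=mcmc,
        )
        frozen = fit_logit_liability(
            y, X, ["alpha", "beta"], df["cage_id"].to_numpy(), Asub,
            slope_covariate=x, freeze_slope=True,
            mcmc=MCMCConfig(n_chains=2, warmup=500,
                            sampling_iterations=9000, thin=6, seed=12),
        )
        for name in ("alpha", "beta", "V_C", "V_A"):
            ks = ks_2samp(basic.pooled(name), frozen.pooled(name)).statistic
            assert ks < 0.1, name

    def test_constant_covariate_rejected(self, small_dataset):
        data, ped, A, cfg = small_dataset
        bad = data.copy()
        bad["nymphal_density"] = 4.0
        with pytest.raises(ValueError, match="constant"):
            fit_animal_model(bad, A, ModelSpec(), MCMCConfig(seed=0))

    def test_missing_ids_in_relatedness_rejected(self, small_dataset):
        data, ped, A, cfg = small_dataset
        from wingmorph.pedigree import RelatednessMatrix

        tiny = RelatednessMatrix(ids=A.ids[:10], A=A.A[:10, :10])
        with pytest.raises(ValueError, match="does not cover"):
            fit_animal_model(data, tiny, ModelSpec(), MCMCConfig(seed=0))

    def test_prior_scale_auto_adjust_floor(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert PriorSpec().resolve_scale(y) == 2.5
        assert PriorSpec(sd_scale=1.7).resolve_scale(y) == 1.7

    def test_mcmc_preset_reproduces_published_protocol(self):
        cfg = MCMCConfig.preset("paper")
        assert (cfg.n_chains, cfg.warmup, cfg.sampling_iterations, cfg.thin) \
            == (2, 50_000, 120_000, 70)
        # kept draws across chains: 2 * 120000 / 70 ~ 3428
        assert cfg.n_chains * (cfg.sampling_iterations // cfg.thin) >= 2000
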