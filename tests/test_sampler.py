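"""Gibbs sampler: kernels against closed-form/grid oracles, prior
recovery, determinism and posterior behaviour."""

import numpy as np
import pytest
from scipy import stats

from bayesmr import (
    MRDataset,
    PriorSpec,
    SamplerConfig,
    SimulationConfig,
    credible_interval,
    impute_X,
    impute_Y,
    initialize,
    run_chain,
    simulate_design,
    update_parameters,
)
from bayesmr.sampler import _coef_conditional
from conftest import make_abc_dataset
from test_model_core import make_state


def empty_dataset():
    return MRDataset(np.empty((0, 3)), np.empty((0, 3)), np.empty(0), np.empty(0, dtype=object))


class TestInitialize:
    def test_stated_initial_values(self, overlap_data, priors):
        state = initialize(overlap_data, priors, seed=0)
        assert np.array_equal(state.beta, np.zeros(3))
        assert np.array_equal(state.alpha, np.ones(4))
        assert np.array_equal(state.delta, np.zeros(4))
        assert np.array_equal(state.omega, np.zeros(4))
        assert np.array_equal(state.sigma, np.ones(4))
        assert np.array_equal(state.U, np.zeros(overlap_data.n))

    def test_imputation_shapes_match_group_sizes(self, overlap_data, priors):
        state = initialize(overlap_data, priors, seed=0)
        assert state.Y_imp.shape == (80,)
        assert state.X_imp.shape == (80, 3)

    def test_deterministic_under_seed(self, overlap_data, priors):
        s1 = initialize(overlap_data, priors, seed=3)
        s2 = initialize(overlap_data, priors, seed=3)
        assert np.array_equal(s1.Y_imp, s2.Y_imp)
        assert np.array_equal(s1.X_imp, s2.X_imp)


class TestImputation:
    def test_impute_y_degenerate_at_mean(self):
        data = make_abc_dataset(n_A=0, n_B=1, n_C=0)
        data.X[0] = [1.0, 1.0, 1.0]
        state = make_state(1, n_B=1, beta=np.array([0.3, 0.3, 0.3]),
                           omega=np.zeros(4), sigma=np.array([1, 1, 1, 1e-15]))
        y = impute_Y(state, data, np.random.default_rng(0))
        assert np.isclose(y[0], 0.9, atol=1e-10)

    def test_impute_x_degenerate_at_mean(self):
        data = make_abc_dataset(n_A=0, n_B=0, n_C=1)
        data.Z[0] = [2.0, 0.0, 2.0]
        state = make_state(1, n_C=1, alpha=np.full(4, 0.5), omega=np.zeros(4),
                           sigma=np.full(4, 1e-15))
        x = impute_X(state, data, np.random.default_rng(0))
        assert np.allclose(x[0], [1.0, 0.0, 1.0], atol=1e-10)

    def test_impute_moments_match_stated_distribution(self):
        """1e5 draws at a fixed state: mean within 4 sd/sqrt(n), sd within 2%."""
        n = 100_000
        Z = np.tile([1.0, 2.0, 0.0], (n, 1))
        X = np.tile([0.5, -0.2, 0.1], (n, 1))
        Y = np.full(n, np.nan)
        data_B = MRDataset(Z, X, Y, np.full(n, "B", dtype=object))
        state = make_state(n, n_B=n, seed=1)
        y = impute_Y(state, data_B, np.random.default_rng(2))
        mu = state.omega[3] + X[0] @ state.beta
        assert abs(y.mean() - mu) < 4 * state.sigma[3] / np.sqrt(n)
        assert abs(y.std() / state.sigma[3] - 1) < 0.02

        data_C = MRDataset(Z, np.full((n, 3), np.nan), np.zeros(n), np.full(n, "C", dtype=object))
        state = make_state(n, n_C=n, seed=3)
        x = impute_X(state, data_C, np.random.default_rng(4))
        mu3 = state.omega[2] + state.alpha[2] * Z[0, 1] + state.alpha[3] * Z[0, 2]
        assert abs(x[:, 2].mean() - mu3) < 4 * state.sigma[2] / np.sqrt(n)
        assert abs(x[:, 2].std() / state.sigma[2] - 1) < 0.02

    def test_empty_groups_are_noops(self, complete_data, priors):
        state = initialize(complete_data, priors, seed=0)
        assert impute_Y(state, complete_data, np.random.default_rng(0)).shape == (0,)
        assert impute_X(state, complete_data, np.random.default_rng(0)).shape == (0, 3)

    def test_impute_y_requires_observed_exposures(self):
        data = make_abc_dataset(n_A=1, n_B=1, n_C=0)
        data.X[1, 0] = np.nan  # violate the B contract
        state = make_state(2, n_B=1)
        with pytest.raises(ValueError, match="observed exposures"):
            impute_Y(state, data, np.random.default_rng(0))


class TestGibbsKernels:
    def test_coefficient_conditional_flat_prior_is_least_squares(self):
        """With a flat-limit prior the conditional mean of a regression
        block equals the normal-equations solution."""
        rng = np.random.default_rng(12)
        D = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = rng.normal(size=50)
        mean, cov = _coef_conditional(D, y, 0.5, np.zeros(3), np.full(3, 1e-12))
        ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(mean, ols, atol=1e-6)
        assert np.allclose(cov, 0.5 * np.linalg.inv(D.T @ D), atol=1e-6)

    def test_latent_confounder_conditional_matches_grid_oracle(self):
        """U_i draws from repeated sweeps (all other parameters pinned by
        near-degenerate priors) match a 1-D quadrature posterior."""
        priors = PriorSpec(
            beta_mean=0.3, beta_sd=1e-7, alpha_mean=0.5, alpha_sd=1e-7,
            delta_mean=0.8, delta_sd=1e-7, omega_mean=0.0, omega_sd=1e-7,
            sigma_shape=1e8, sigma_scale=0.5 * (1e8 + 1),  # mode pins sigma at 0.5
        )
        Z = np.array([[1.0, 2.0, 0.0]])
        X = np.array([[0.9, 1.3, 0.7]])
        Y = np.array([1.4])
        data = MRDataset(Z, X, Y, np.array(["A"], dtype=object))
        config = SamplerConfig(n_iter=2, n_warmup=1)
        rng = np.random.default_rng(0)
        state = initialize(data, priors, seed=0)
        draws = np.empty(4000)
        for i in range(draws.size):
            state = update_parameters(state, data, priors, config, rng)
            draws[i] = state.U[0]

        b, a, d, s = 0.3, 0.5, 0.8, 0.5
        mx = np.array([a * 1.0, a * 2.0, a * 2.0 + a * 0.0])
        my = b * X[0].sum()
        u = np.linspace(-2, 2, 4001)
        logp = stats.norm.logpdf(u, 0, np.sqrt(0.1))
        for k in range(3):
            logp += stats.norm.logpdf(X[0, k], mx[k] + d * u, s)
        logp += stats.norm.logpdf(Y[0], my + d * u, s)
        w = np.exp(logp - logp.max())
        w /= w.sum()
        mean_oracle = float(u @ w)
        var_oracle = float((u - mean_oracle) ** 2 @ w)
        assert abs(draws.mean() - mean_oracle) < 5 * np.sqrt(var_oracle / draws.size)
        assert abs(draws.var() / var_oracle - 1) < 0.15

    def test_prior_recovery_with_empty_data(self, priors):
        """Repeated sweeps on an empty dataset sample the prior for every
        parameter (KS tests at the 1% level; sigma draws thinned because
        the Metropolis update is autocorrelated)."""
        data = empty_dataset()
        config = SamplerConfig(n_iter=2, n_warmup=1)
        rng = np.random.default_rng(123)
        state = make_state(0)
        n_sweeps = 50_000
        alpha = np.empty(n_sweeps)
        beta = np.empty(n_sweeps)
        sigma = np.empty(n_sweeps)
        for i in range(n_sweeps):
            state = update_parameters(state, data, priors, config, rng)
            alpha[i] = state.alpha[0]
            beta[i] = state.beta[0]
            sigma[i] = state.sigma[0]
        assert abs(alpha.mean() - 1.0) < 4 * 0.3 / np.sqrt(n_sweeps)
        assert abs(alpha.std() - 0.3) < 0.01
        assert stats.kstest(alpha, stats.norm(1, 0.3).cdf).pvalue > 0.01
        assert stats.kstest(beta, stats.norm(0, 10).cdf).pvalue > 0.01
        thinned = sigma[::100]
        assert stats.kstest(thinned, stats.invgamma(3, scale=2).cdf).pvalue > 0.01

    def test_update_rejects_nonpositive_sigma_states_gracefully(self, priors):
        # a state with sigma <= 0 has zero posterior density; log_prior says so
        from bayesmr import log_prior

        state = make_state(0, sigma=np.array([0.0, 1, 1, 1]))
        assert log_prior(state, priors) == -np.inf


def _tv_distance(draws, grid, log_marginal):
    """Total variation between draw histogram and a grid density."""
    p = np.exp(log_marginal - log_marginal.max())
    p /= p.sum()
    edges = np.concatenate([[grid[0] - np.inf], 0.5 * (grid[1:] + grid[:-1]), [np.inf]])
    counts, _ = np.histogram(draws, bins=edges)
    q = counts / counts.sum()
    return 0.5 * np.abs(p - q).sum()


class TestGridOracleEquivalence:
    """On a 2-row dataset with two free parameters (b1 and sigma_Y; the
    rest pinned by near-degenerate priors and zeroed exposure columns)
    the sampler's marginals must match brute-force grid posteriors."""

    @pytest.mark.parametrize("sigma_update", ["metropolis-on-sd", "conjugate-on-variance"])
    def test_marginals_match_grid(self, sigma_update):
        x1 = np.array([1.0, -0.8])
        y = np.array([0.55, -0.3])
        Z = np.array([[1.0, 1.0, 1.0], [2.0, 0.0, 1.0]])
        X = np.column_stack([x1, np.zeros(2), np.zeros(2)])
        data = MRDataset(Z, X, y, np.array(["A", "A"], dtype=object))
        priors = PriorSpec(
            delta_sd=1e-7, omega_sd=1e-7,
            sigma_param="sd" if sigma_update == "metropolis-on-sd" else "variance",
        )
        config = SamplerConfig(
            n_iter=42_000, n_warmup=2_000, seed=8, sigma_update=sigma_update
        )
        summary = run_chain(data, priors, config)
        b_draws = summary.param("beta1")
        s_draws = summary.param("sigmaY")

        b_grid = np.linspace(-6, 6, 401)
        s_grid = np.linspace(1e-3, 8, 400)
        B, S = np.meshgrid(b_grid, s_grid, indexing="ij")
        logp = stats.norm.logpdf(B, 0, 10)
        if sigma_update == "metropolis-on-sd":
            logp += stats.invgamma.logpdf(S, 3, scale=2)
        else:
            logp += stats.invgamma.logpdf(S**2, 3, scale=2) + np.log(2 * S)
        for xi, yi in zip(x1, y):
            logp += stats.norm.logpdf(yi, B * xi, S)
        joint = np.exp(logp - logp.max())
        log_b = np.log(joint.sum(axis=1) + 1e-300)
        log_s = np.log(joint.sum(axis=0) + 1e-300)
        tv_b = _tv_distance(b_draws, b_grid, log_b)
        tv_s = _tv_distance(s_draws, s_grid, log_s)
        assert tv_b < 0.05, f"TV(beta1) = {tv_b:.3f}"
        assert tv_s < 0.05, f"TV(sigmaY) = {tv_s:.3f}"


class TestRunChain:
    def test_deterministic_under_seed(self, priors):
        cfg = SimulationConfig(overlap_rate=0.5, n_population=150, n_study=60, seed=21)
        data = simulate_design(cfg)
        sc = SamplerConfig(n_iter=300, n_warmup=100, seed=5)
        s1 = run_chain(data, priors, sc)
        s2 = run_chain(data, priors, sc)
        assert np.array_equal(s1.draws, s2.draws)

    def test_full_overlap_is_plain_one_sample_fit(self, complete_data, priors):
        """With no missing data the imputation branch never executes, so
        the literal and full-conditional schemes coincide exactly."""
        lit = run_chain(complete_data, priors, SamplerConfig(n_iter=200, n_warmup=50, imputation="literal"))
        fc = run_chain(complete_data, priors, SamplerConfig(n_iter=200, n_warmup=50, imputation="full-conditional"))
        assert np.array_equal(lit.draws, fc.draws)

    def test_parameter_recovery_full_overlap(self, priors):
        """Posterior means recover beta = 0.3 at the study scale (n=400,
        strong instruments, strong confounding); averaged over a few
        datasets to sit above the per-dataset sampling noise."""
        sc = SamplerConfig(n_iter=1000, n_warmup=300)
        means = []
        for seed in range(6):
            cfg = SimulationConfig(overlap_rate=1.0, seed=100 + seed)
            data = simulate_design(cfg)
            summary = run_chain(data, priors, sc)
            m, _ = summary.beta_estimates()
            means.append(m)
            assert np.all(np.abs(m - 0.3) < 0.08)  # every fit within ~4 sampling sds
        assert np.all(np.abs(np.mean(means, axis=0) - 0.3) < 0.02)

    def test_posterior_sd_non_increasing_in_overlap(self, priors):
        """More overlap means less imputation, hence tighter posteriors."""
        sc = SamplerConfig(n_iter=600, n_warmup=200)
        rates = [0.0, 0.2, 0.6, 1.0]
        mean_sd = []
        for rate in rates:
            sds = []
            for rep in range(8):
                cfg = SimulationConfig(overlap_rate=rate, seed=3000 + rep)
                data = simulate_design(cfg)
                summary = run_chain(data, priors, sc)
                sds.append(summary.sd[summary.names.index("beta1")])
            mean_sd.append(np.mean(sds))
        assert all(a >= b for a, b in zip(mean_sd, mean_sd[1:])), mean_sd

    def test_empty_dataset_rejected(self, priors):
        with pytest.raises(ValueError, match="no rows"):
            run_chain(empty_dataset(), priors, SamplerConfig(n_iter=10, n_warmup=1))

    def test_multichain_diagnostics(self, complete_data, priors):
        sc = SamplerConfig(n_iter=400, n_warmup=100, n_chains=2, seed=2)
        summary = run_chain(complete_data, priors, sc)
        assert summary.draws.shape == (2, 300, 19)
        assert summary.pooled.shape == (600, 19)
        assert np.all(np.isfinite(summary.rhat))
        assert np.all(summary.rhat < 1.2)
        assert np.all(summary.ess > 20)
        frame = summary.to_frame()
        assert list(frame.columns) == ["mean", "sd", "ci_low", "ci_high", "rhat", "ess"]

    def test_single_chain_split_rhat_is_finite(self, complete_data, priors):
        sc = SamplerConfig(n_iter=400, n_warmup=100, seed=4)
        summary = run_chain(complete_data, priors, sc)
        assert np.all(np.isfinite(summary.rhat))
        assert np.all(summary.rhat < 1.3)

    def test_interval_contract(self, complete_data, priors):
        sc = SamplerConfig(n_iter=400, n_warmup=100, seed=3)
        summary = run_chain(complete_data, priors, sc)
        assert np.all(summary.ci[:, 0] <= summary.ci[:, 1])
        inside = (
            (summary.pooled >= summary.ci[:, 0]) & (summary.pooled <= summary.ci[:, 1])
        ).mean(axis=0)
        assert np.all(np.abs(inside - 0.95) <= 2.0 / summary.pooled.shape[0] + 1e-9)


class TestCredibleInterval:
    def test_order_statistics_example(self):
        lo, hi = credible_interval(np.arange(1, 101, dtype=float), 0.95)
        assert np.isclose(lo, 3.475)
        assert np.isclose(hi, 97.525)

    def test_constant_draws(self):
        assert credible_interval(np.full(10, 2.5), 0.95) == (2.5, 2.5)

    def test_normal_quantile_oracle(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = credible_interval(draws, 0.95)
        assert abs(lo + 1.959964) < 0.01
        assert abs(hi - 1.959964) < 0.01

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.empty(0), 0.95)
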