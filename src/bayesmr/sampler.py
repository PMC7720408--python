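"""Markov chain scheme: iterative imputation plus Gibbs parameter updates.

Each iteration performs three steps on the current parameter state:

1. *Impute*: draw Y* for group-B rows from N(wY + b.x, sY^2) using their
   observed exposures, and X* for group-C rows from the exposure
   equations N(w + a.z, s^2) using their observed instruments.  The
   latent confounder and the noise terms have mean zero and are omitted
   from these imputation means; the observed Y of group-C rows is not
   conditioned on.  This is the scheme as stated, not the full
   conditional of the missing data (a full-conditional variant is
   available via ``SamplerConfig.imputation`` for sensitivity analysis).
2. *Merge*: substitute the imputations to obtain a complete dataset.
3. *Update*: one sweep of MCMC targeting the complete-data posterior —
   exact Gaussian full-conditional draws for the four regression blocks
   (exposure equations and outcome equation), exact Gaussian draws for
   each latent U_i, and either random-walk Metropolis on log(sigma)
   (Inv-Gamma prior on the sd, the default) or an exact inverse-gamma
   draw (Inv-Gamma prior on the variance).

With no missing data (100% overlap) step 1 is a no-op and the scheme is
a plain one-sample Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .datagen import MRDataset
from .model_core import ParameterState, PriorSpec, exposure_means, outcome_mean

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "PARAM_NAMES",
    "initialize",
    "impute_Y",
    "impute_X",
    "update_parameters",
    "run_chain",
    "credible_interval",
]

#: Order of the retained parameters in the draw matrix.
PARAM_NAMES = [
    "beta1", "beta2", "beta3",
    "alpha1", "alpha2", "alpha3", "alpha4",
    "delta1", "delta2", "delta3", "delta4",
    "omega1", "omega2", "omega3", "omegaY",
    "sigma1", "sigma2", "sigma3", "sigmaY",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.

    ``sigma_update`` selects "metropolis-on-sd" (random-walk Metropolis on
    log sigma against the Inv-Gamma prior on the sd; default) or
    "conjugate-on-variance" (exact inverse-gamma draw, prior on the
    variance).  ``imputation`` selects the literal step-2 scheme
    ("literal", default) or the full conditional of the missing data
    given everything else ("full-conditional").
    """

    n_iter: int = 3000
    n_warmup: int = 1000
    n_chains: int = 1
    seed: int = 0
    sigma_update: str = "metropolis-on-sd"
    imputation: str = "full-conditional"
    credible_level: float = 0.95
    mh_step: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.n_warmup < self.n_iter:
            raise ValueError("need 0 <= n_warmup < n_iter")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must be in (0, 1)")
        if self.sigma_update not in ("metropolis-on-sd", "conjugate-on-variance"):
            raise ValueError(f"unknown sigma_update {self.sigma_update!r}")
        if self.imputation not in ("literal", "full-conditional"):
            raise ValueError(f"unknown imputation {self.imputation!r}")
        if self.n_chains < 1 or self.mh_step <= 0:
            raise ValueError("n_chains must be >= 1 and mh_step positive")


# ---------------------------------------------------------------------------
# Step 1/2: imputation
# ---------------------------------------------------------------------------

def impute_Y(state: ParameterState, data: MRDataset, rng: np.random.Generator) -> np.ndarray:
    """Draw Y* for group-B rows from N(wY + b.x, sY^2).

    Uses the observed exposures of group B; U and the noise term have
    zero mean and do not appear.  Returns an empty vector when B is empty.
    """
    X_B = data.X[data.mask("B")]
    if np.isnan(X_B).any():
        raise ValueError("group-B rows must have observed exposures")
    if X_B.shape[0] == 0:
        return np.empty(0)
    mean = outcome_mean(state, X_B)
    return rng.normal(mean, state.sigma[3])


def impute_X(state: ParameterState, data: MRDataset, rng: np.random.Generator) -> np.ndarray:
    """Draw X* for group-C rows from the exposure equations given Z.

    X*_k ~ N(w_k + (a.z)_k, s_k^2) independently across rows and columns;
    the observed outcome of group C is not conditioned on.  Returns an
    empty (0, 3) matrix when C is empty.
    """
    Z_C = data.Z[data.mask("C")]
    if Z_C.shape[0] == 0:
        return np.empty((0, 3))
    mean = exposure_means(state, Z_C)
    return rng.normal(mean, state.sigma[:3])


def _impute_X_full_conditional(
    state: ParameterState, Z_C: np.ndarray, Y_C: np.ndarray, U_C: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Full conditional of X* given (Z, Y, U) and parameters.

    Combines the exposure-equation prior N(mu_x, diag(s^2)) with the
    outcome likelihood Y ~ N(wY + b.x + d4 u, sY^2); the posterior is
    Gaussian with constant precision  diag(1/s^2) + b b'/sY^2.
    """
    if Z_C.shape[0] == 0:
        return np.empty((0, 3))
    b, s, sY = state.beta, state.sigma[:3], state.sigma[3]
    mu = exposure_means(state, Z_C) + np.outer(U_C, state.delta[:3])
    prec = np.diag(1.0 / s**2) + np.outer(b, b) / sY**2
    cov = np.linalg.inv(prec)
    resid = (Y_C - state.omega[3] - state.delta[3] * U_C) / sY**2
    mean = (mu / s**2 + np.outer(resid, b)) @ cov.T
    L = np.linalg.cholesky(cov)
    return mean + rng.standard_normal(mean.shape) @ L.T


# ---------------------------------------------------------------------------
# Gibbs kernels
# ---------------------------------------------------------------------------

def _coef_conditional(D, y, sigma2, prior_mean, prior_prec):
    """Mean and covariance of the Gaussian full conditional of a
    regression block with response variance ``sigma2`` and independent
    Gaussian priors (``prior_prec`` is the diagonal prior precision)."""
    A = D.T @ D / sigma2 + np.diag(prior_prec)
    b = D.T @ y / sigma2 + prior_prec * prior_mean
    cov = np.linalg.inv(A)
    return cov @ b, cov

def _draw_coef_block(rng, D, y, sigma2, prior_mean, prior_prec):
    A = D.T @ D / sigma2
    A[np.diag_indices_from(A)] += prior_prec
    b = D.T @ y / sigma2 + prior_prec * prior_mean
    L = np.linalg.cholesky(A)
    # mean = A^{-1} b via two triangular solves, then add N(0, A^{-1}) noise
    w = np.linalg.solve(L, b)
    z = rng.standard_normal(len(b))
    return np.linalg.solve(L.T, w + z)


def _log_sigma_target(lam: float, n: int, ssr: float, shape: float, scale: float) -> float:
    # density of lambda = log(sigma) under Inv-Gamma(shape, scale) on the sd,
    # times the Gaussian likelihood of n residuals with SSR given
    sigma = np.exp(lam)
    return (-float(n) - (shape + 1.0) + 1.0) * lam - ssr / (2.0 * sigma**2) - scale / sigma


def _draw_sigma(rng, sigma, n, ssr, priors: PriorSpec, config: SamplerConfig):
    """Update one noise sd given its residual sum of squares."""
    if config.sigma_update == "conjugate-on-variance":
        shape = priors.sigma_shape + 0.5 * n
        scale = priors.sigma_scale + 0.5 * ssr
        return float(np.sqrt(scale / rng.gamma(shape, 1.0)))
    lam = np.log(sigma)
    prop = lam + config.mh_step * rng.standard_normal()
    logr = _log_sigma_target(prop, n, ssr, priors.sigma_shape, priors.sigma_scale) - \
        _log_sigma_target(lam, n, ssr, priors.sigma_shape, priors.sigma_scale)
    if np.log(rng.random()) < logr:
        return float(np.exp(prop))
    return float(sigma)


def update_parameters(
    state: ParameterState,
    data: MRDataset,
    priors: PriorSpec,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> ParameterState:
    """One sweep of the complete-data MCMC update (step 4).

    The dataset's missing cells are filled with the state's current
    imputations before updating.  Returns a new state with fresh
    coefficient, U and sigma values (imputations are untouched).
    Satisfies detailed balance with respect to the complete-data
    posterior for fixed imputations.
    """
    from .model_core import complete_arrays

    Z, Xc, Yc = complete_arrays(state, data)
    ws = _Workspace(Z, Xc, Yc)
    new = ParameterState(
        beta=state.beta, alpha=state.alpha, delta=state.delta,
        omega=state.omega, sigma=state.sigma, U=state.U.copy(),
        X_imp=state.X_imp, Y_imp=state.Y_imp,
    )
    _sweep(new, ws, priors, config, rng)
    if not (np.all(np.isfinite(new.sigma)) and np.all(np.isfinite(new.beta))):
        raise FloatingPointError("non-finite values in parameter update")
    return new


class _Workspace:
    """Preallocated design matrices for the Gibbs sweep on complete data."""

    def __init__(self, Z: np.ndarray, Xc: np.ndarray, Yc: np.ndarray):
        n = Z.shape[0]
        self.n = n
        self.Z, self.Xc, self.Yc = Z, Xc, Yc
        one = np.ones(n)
        self.D1 = np.column_stack([one, Z[:, 0], np.zeros(n)])
        self.D2 = np.column_stack([one, Z[:, 1], np.zeros(n)])
        self.D3 = np.column_stack([one, Z[:, 1], Z[:, 2], np.zeros(n)])
        self.D4 = np.column_stack([one, Xc, np.zeros(n)])

    def set_X(self, rows, values) -> None:
        self.Xc[rows] = values
        self.D4[rows, 1:4] = values


def _sweep(state: ParameterState, ws: _Workspace, priors: PriorSpec,
           config: SamplerConfig, rng: np.random.Generator) -> None:
    """In-place Gibbs sweep on ``state`` given complete data in ``ws``."""
    n = ws.n
    u = state.U
    if n == 0:
        # no data: every full conditional collapses to its prior
        state.omega = rng.normal(priors.omega_mean, priors.omega_sd, 4)
        state.alpha = rng.normal(priors.alpha_mean, priors.alpha_sd, 4)
        state.delta = rng.normal(priors.delta_mean, priors.delta_sd, 4)
        state.beta = rng.normal(priors.beta_mean, priors.beta_sd, 3)
        for k in range(4):
            state.sigma[k] = _draw_sigma(rng, state.sigma[k], 0, 0.0, priors, config)
        return

    pm_o, pp_o = priors.omega_mean, 1.0 / priors.omega_sd**2
    pm_a, pp_a = priors.alpha_mean, 1.0 / priors.alpha_sd**2
    pm_d, pp_d = priors.delta_mean, 1.0 / priors.delta_sd**2
    pm_b, pp_b = priors.beta_mean, 1.0 / priors.beta_sd**2
    s2 = state.sigma**2

    # --- regression blocks (omega, alpha/beta, delta per equation) -----
    ws.D1[:, 2] = u
    th = _draw_coef_block(rng, ws.D1, ws.Xc[:, 0], s2[0],
                          np.array([pm_o, pm_a, pm_d]), np.array([pp_o, pp_a, pp_d]))
    state.omega[0], state.alpha[0], state.delta[0] = th

    ws.D2[:, 2] = u
    th = _draw_coef_block(rng, ws.D2, ws.Xc[:, 1], s2[1],
                          np.array([pm_o, pm_a, pm_d]), np.array([pp_o, pp_a, pp_d]))
    state.omega[1], state.alpha[1], state.delta[1] = th

    ws.D3[:, 3] = u
    th = _draw_coef_block(rng, ws.D3, ws.Xc[:, 2], s2[2],
                          np.array([pm_o, pm_a, pm_a, pm_d]),
                          np.array([pp_o, pp_a, pp_a, pp_d]))
    state.omega[2], state.alpha[2], state.alpha[3], state.delta[2] = th

    ws.D4[:, 4] = u
    th = _draw_coef_block(rng, ws.D4, ws.Yc, s2[3],
                          np.array([pm_o, pm_b, pm_b, pm_b, pm_d]),
                          np.array([pp_o, pp_b, pp_b, pp_b, pp_d]))
    state.omega[3] = th[0]
    state.beta = th[1:4]
    state.delta[3] = th[4]

    # --- latent confounders -------------------------------------------
    d = state.delta
    mx = exposure_means(state, ws.Z)
    my = outcome_mean(state, ws.Xc)
    rx = ws.Xc - mx          # residuals without the U term
    ry = ws.Yc - my
    prec = 1.0 / priors.u_var + np.sum(d**2 / s2)
    num = rx @ (d[:3] / s2[:3]) + ry * (d[3] / s2[3])
    sd_u = 1.0 / np.sqrt(prec)
    state.U = num / prec + sd_u * rng.standard_normal(n)
    u = state.U

    # --- noise sds -----------------------------------------------------
    ex = rx - np.outer(u, d[:3])
    ey = ry - d[3] * u
    for k in range(3):
        state.sigma[k] = _draw_sigma(rng, state.sigma[k], n, float(ex[:, k] @ ex[:, k]),
                                     priors, config)
    state.sigma[3] = _draw_sigma(rng, state.sigma[3], n, float(ey @ ey), priors, config)


# ---------------------------------------------------------------------------
# Initialization and the outer loop
# ---------------------------------------------------------------------------

def initialize(data: MRDataset, priors: PriorSpec, seed: int) -> ParameterState:
    """Initial state: beta=0, alpha at its prior mean, delta=0, omega=0,
    sigma=1, U=0; imputations drawn once from the step-2 formulas at
    these values.  Deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    state = ParameterState(
        beta=np.zeros(3),
        alpha=np.full(4, priors.alpha_mean),
        delta=np.zeros(4),
        omega=np.zeros(4),
        sigma=np.ones(4),
        U=np.zeros(data.n),
        X_imp=np.empty((data.n_C, 3)),
        Y_imp=np.empty(data.n_B),
    )
    state.Y_imp = impute_Y(state, data, rng)
    state.X_imp = impute_X(state, data, rng)
    return state


def run_chain(data: MRDataset, priors: PriorSpec, config: SamplerConfig) -> "PosteriorSummary":
    """Run the full scheme and summarize the retained draws.

    Iterates impute -> merge -> update for ``config.n_iter`` iterations
    per chain, discards ``config.n_warmup``, and concatenates post-warmup
    draws across chains.  Reproducible per (seed, chain index).
    """
    data.validate()
    if data.n == 0:
        raise ValueError("dataset has no rows in any of groups A, B, C")
    n_keep = config.n_iter - config.n_warmup
    draws = np.empty((config.n_chains, n_keep, len(PARAM_NAMES)))
    idx_B = np.flatnonzero(data.mask("B"))
    idx_C = np.flatnonzero(data.mask("C"))
    X_B = data.X[idx_B]
    Z_C = data.Z[idx_C]
    Y_C = data.Y[idx_C]

    for chain in range(config.n_chains):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(chain,))
        init_seed, sweep_seed = ss.generate_state(2)
        rng = np.random.default_rng(sweep_seed)
        state = initialize(data, priors, int(init_seed))

        X0 = data.X.copy()
        Y0 = data.Y.copy()
        X0[idx_C] = state.X_imp
        Y0[idx_B] = state.Y_imp
        ws = _Workspace(data.Z, X0, Y0)

        for t in range(config.n_iter):
            # step 1-2: impute and merge
            if idx_B.size:
                mean_B = outcome_mean(state, X_B)
                if config.imputation == "full-conditional":
                    mean_B = mean_B + state.delta[3] * state.U[idx_B]
                ws.Yc[idx_B] = rng.normal(mean_B, state.sigma[3])
            if idx_C.size:
                if config.imputation == "literal":
                    x_star = rng.normal(exposure_means(state, Z_C), state.sigma[:3])
                else:
                    x_star = _impute_X_full_conditional(
                        state, Z_C, Y_C, state.U[idx_C], rng)
                ws.set_X(idx_C, x_star)
            # step 4: parameter sweep on the complete data
            _sweep(state, ws, priors, config, rng)
            if t >= config.n_warmup:
                k = t - config.n_warmup
                row = draws[chain, k]
                row[0:3] = state.beta
                row[3:7] = state.alpha
                row[7:11] = state.delta
                row[11:15] = state.omega
                row[15:19] = state.sigma
        if not np.all(np.isfinite(draws[chain])):
            raise FloatingPointError("non-finite draws in chain %d" % chain)
        # (delta, U) -> (-delta, -U) leaves the likelihood invariant, so the
        # sign of the confounder loadings is a convention; align each chain
        # to a positive average loading so multi-chain summaries are comparable
        if draws[chain, :, 7:11].mean() < 0:
            draws[chain, :, 7:11] *= -1.0

    return PosteriorSummary(names=list(PARAM_NAMES), draws=draws, level=config.credible_level)


def credible_interval(draws: np.ndarray, level: float = 0.95):
    """Equal-tailed credible interval (percentiles with linear
    interpolation between order statistics)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("need at least one draw")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return float(lo), float(hi)


@dataclass
class PosteriorSummary:
    """Posterior summaries of the retained draws.

    ``draws`` has shape (n_chains, n_kept, n_params) in the order of
    ``names``.  Summaries pool draws across chains; split-Rhat and bulk
    effective sample size are computed lazily (via ArviZ).
    """

    names: list
    draws: np.ndarray
    level: float = 0.95

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @cached_property
    def mean(self) -> np.ndarray:
        return self.pooled.mean(axis=0)

    @cached_property
    def sd(self) -> np.ndarray:
        return self.pooled.std(axis=0, ddof=1)

    @cached_property
    def ci(self) -> np.ndarray:
        """(n_params, 2) equal-tailed intervals at ``level``."""
        tail = 100.0 * (1.0 - self.level) / 2.0
        return np.percentile(self.pooled, [tail, 100.0 - tail], axis=0).T

    @cached_property
    def _diagnostics(self):
        import arviz as az

        draws = self.draws
        if draws.shape[0] == 1:
            # split the single chain in half so Rhat is the split statistic
            half = draws.shape[1] // 2
            split = np.stack([draws[0, :half], draws[0, half:2 * half]])
        else:
            split = draws
        rhat = az.rhat(az.convert_to_dataset(split))["x"].to_numpy()
        ess = az.ess(az.convert_to_dataset(draws))["x"].to_numpy()
        return rhat, ess

    @property
    def rhat(self) -> np.ndarray:
        return self._diagnostics[0]

    @property
    def ess(self) -> np.ndarray:
        return self._diagnostics[1]

    def param(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter."""
        return self.pooled[:, self.names.index(name)]

    def beta_estimates(self):
        """(mean, ci) for the three causal effects, shapes (3,), (3, 2)."""
        idx = [self.names.index(f"beta{k}") for k in (1, 2, 3)]
        return self.mean[idx], self.ci[idx]

    def to_frame(self, diagnostics: bool = True) -> pd.DataFrame:
        cols = {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci[:, 0],
            "ci_high": self.ci[:, 1],
        }
        if diagnostics:
            cols["rhat"] = self.rhat
            cols["ess"] = self.ess
        return pd.DataFrame(cols, index=pd.Index(self.names, name="parameter"))
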