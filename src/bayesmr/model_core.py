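"""Structural model, priors and log-densities.

The complete-data likelihood factorizes over individuals and over the
four Gaussian regression equations (three exposures and the outcome);
see :mod:`bayesmr.datagen` for the generative equations.  The latent
confounder U enters as one scalar per individual with a fixed N(0, 0.1)
prior: its scale is not identifiable from the likelihood, so the
confounding magnitude is carried by the delta coefficients.

Priors (iid across components):

* beta  ~ N(0, 10^2)          — diffuse on the causal effects
* alpha ~ N(1, 0.3^2)         — instrument strengths bounded away from 0
* delta, omega ~ N(0, 10^2)   — diffuse
* sigma ~ Inv-Gamma(3, 2), placed on the standard deviation by default;
  a variance-scale option exists for conjugate sampling.
* U_i ~ N(0, 0.1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datagen import U_VARIANCE, MRDataset

__all__ = [
    "ModelGraph",
    "PriorSpec",
    "ParameterState",
    "exposure_means",
    "outcome_mean",
    "complete_arrays",
    "complete_data_loglik",
    "log_prior",
    "log_posterior_unnorm",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelGraph:
    """Instrument-to-exposure incidence.

    ``loadings[j, k]`` is True when instrument Z_{j+1} loads on exposure
    X_{k+1}.  The default encodes Z1->X1, Z2->X2, Z2->X3, Z3->X3, i.e.
    four free instrument strengths with Z2 pleiotropic.  Every instrument
    must load on at least one exposure and every exposure must have at
    least one instrument (the relevance assumption).
    """

    loadings: np.ndarray = field(
        default_factory=lambda: np.array(
            [[True, False, False], [False, True, True], [False, False, True]]
        )
    )

    def __post_init__(self) -> None:
        L = np.asarray(self.loadings, dtype=bool)
        object.__setattr__(self, "loadings", L)
        if L.shape != (3, 3):
            raise ValueError("loadings must be 3x3")
        if not L.any(axis=1).all():
            raise ValueError("every instrument must load on at least one exposure")
        if not L.any(axis=0).all():
            raise ValueError("every exposure must have at least one instrument")

    @property
    def n_alpha(self) -> int:
        return int(self.loadings.sum())


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior; see the module docstring for defaults."""

    beta_mean: float = 0.0
    beta_sd: float = 10.0
    alpha_mean: float = 1.0
    alpha_sd: float = 0.3
    delta_mean: float = 0.0
    delta_sd: float = 10.0
    omega_mean: float = 0.0
    omega_sd: float = 10.0
    sigma_shape: float = 3.0
    sigma_scale: float = 2.0
    #: "sd" places Inv-Gamma(shape, scale) on sigma itself; "variance"
    #: places it on sigma^2 (the conjugate parameterization).
    sigma_param: str = "sd"
    u_var: float = U_VARIANCE

    def __post_init__(self) -> None:
        for name in ("beta_sd", "alpha_sd", "delta_sd", "omega_sd", "sigma_shape", "sigma_scale", "u_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_param not in ("sd", "variance"):
            raise ValueError(f"sigma_param must be 'sd' or 'variance', got {self.sigma_param!r}")

    def log_sigma_prior(self, sigma: np.ndarray) -> float:
        """Log prior density of the noise sds, as a density in sigma."""
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            return -np.inf
        dist = stats.invgamma(self.sigma_shape, scale=self.sigma_scale)
        if self.sigma_param == "sd":
            return float(np.sum(dist.logpdf(sigma)))
        # density of sigma induced by Inv-Gamma on the variance
        return float(np.sum(dist.logpdf(sigma**2) + np.log(2.0 * sigma)))


@dataclass
class ParameterState:
    """One point in the augmented parameter space.

    Holds the structural coefficients, the per-individual latent
    confounders U, and the current imputations: ``Y_imp`` for group-B
    rows (outcome missing) and ``X_imp`` for group-C rows (exposures
    missing).
    """

    beta: np.ndarray   # (3,) causal effects
    alpha: np.ndarray  # (4,) instrument strengths
    delta: np.ndarray  # (4,) confounder effects (delta[3] acts on Y)
    omega: np.ndarray  # (4,) intercepts (omega[3] is the outcome intercept)
    sigma: np.ndarray  # (4,) noise sds (sigma[3] is the outcome sd)
    U: np.ndarray      # (n,) latent confounders
    X_imp: np.ndarray  # (n_C, 3) imputed exposures
    Y_imp: np.ndarray  # (n_B,) imputed outcomes

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).reshape(3)
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(4)
        self.delta = np.asarray(self.delta, dtype=float).reshape(4)
        self.omega = np.asarray(self.omega, dtype=float).reshape(4)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(4)
        self.U = np.asarray(self.U, dtype=float)
        self.X_imp = np.asarray(self.X_imp, dtype=float).reshape(-1, 3)
        self.Y_imp = np.asarray(self.Y_imp, dtype=float).reshape(-1)

    def check_dims(self, data: MRDataset) -> None:
        if self.U.shape != (data.n,):
            raise ValueError(f"U has length {self.U.shape[0]}, expected {data.n}")
        if self.X_imp.shape[0] != data.n_C:
            raise ValueError(f"X_imp has {self.X_imp.shape[0]} rows, expected {data.n_C}")
        if self.Y_imp.shape[0] != data.n_B:
            raise ValueError(f"Y_imp has length {self.Y_imp.shape[0]}, expected {data.n_B}")


def exposure_means(state: ParameterState, Z: np.ndarray) -> np.ndarray:
    """Structural means of (X1, X2, X3) given Z, excluding the U term."""
    w, a = state.omega, state.alpha
    m = np.empty((Z.shape[0], 3))
    m[:, 0] = w[0] + a[0] * Z[:, 0]
    m[:, 1] = w[1] + a[1] * Z[:, 1]
    m[:, 2] = w[2] + a[2] * Z[:, 1] + a[3] * Z[:, 2]
    return m


def outcome_mean(state: ParameterState, X: np.ndarray) -> np.ndarray:
    """Structural mean of Y given X, excluding the U term."""
    return state.omega[3] + X @ state.beta


def complete_arrays(state: ParameterState, data: MRDataset):
    """(Z, X, Y) with the current imputations substituted for missing cells."""
    state.check_dims(data)
    X = data.X.copy()
    Y = data.Y.copy()
    X[data.mask("C")] = state.X_imp
    Y[data.mask("B")] = state.Y_imp
    return data.Z, X, Y


def _normal_logpdf_sum(resid: np.ndarray, sd: float) -> float:
    return float(-0.5 * resid.size * _LOG_2PI - resid.size * np.log(sd) - np.sum(resid**2) / (2.0 * sd**2))


def complete_data_loglik(state: ParameterState, data: MRDataset) -> float:
    """Complete-data log likelihood, with imputations treated as observed.

    Sums, over individuals, the log densities of the three exposure
    equations and the outcome equation conditional on (Z, U).
    """
    Z, X, Y = complete_arrays(state, data)
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing cells remain after substituting imputations")
    mx = exposure_means(state, Z) + np.outer(state.U, state.delta[:3])
    my = outcome_mean(state, X) + state.delta[3] * state.U
    total = 0.0
    for k in range(3):
        total += _normal_logpdf_sum(X[:, k] - mx[:, k], state.sigma[k])
    total += _normal_logpdf_sum(Y - my, state.sigma[3])
    return total


def log_prior(state: ParameterState, priors: PriorSpec) -> float:
    """Log prior of the state, including the U ~ N(0, 0.1) term.

    Returns -inf (a rejected state, not an exception) when any sigma
    is non-positive.
    """
    if np.any(state.sigma <= 0):
        return -np.inf
    lp = _normal_logpdf_sum(state.beta - priors.beta_mean, priors.beta_sd)
    lp += _normal_logpdf_sum(state.alpha - priors.alpha_mean, priors.alpha_sd)
    lp += _normal_logpdf_sum(state.delta - priors.delta_mean, priors.delta_sd)
    lp += _normal_logpdf_sum(state.omega - priors.omega_mean, priors.omega_sd)
    lp += priors.log_sigma_prior(state.sigma)
    if state.U.size:
        lp += _normal_logpdf_sum(state.U, np.sqrt(priors.u_var))
    return lp


def log_posterior_unnorm(state: ParameterState, data: MRDataset, priors: PriorSpec) -> float:
    """Unnormalized log posterior: log prior + complete-data log likelihood."""
    lp = log_prior(state, priors)
    if not np.isfinite(lp):
        return lp
    if data.n == 0:
        return lp
    return lp + complete_data_loglik(state, data)
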