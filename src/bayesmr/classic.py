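"""Classic Mendelian randomization comparators.

Two frequentist estimators of the three causal effects:

* multivariable two-stage least squares (2SLS) on complete one-sample
  data — exposures are regressed on the instruments, then the outcome on
  the fitted exposures, with classical homoskedastic standard errors;
* multivariable inverse-variance weighted (IVW) estimation from summary
  statistics — per-instrument exposure associations (gamma_hat, from the
  exposure-study rows) and outcome associations (Gamma_hat, from the
  outcome-study rows) are combined by weighted least squares with
  weights 1/se(Gamma_hat)^2.

For a partially overlapping design, IVW is applied to the non-overlapping
rows only (groups B and C), which makes it a valid two-sample analysis
at the price of discarding the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.sandbox.regression.gmm import IV2SLS

from .datagen import MRDataset

__all__ = [
    "ClassicEstimate",
    "SummaryStats",
    "fit_2sls",
    "compute_summary_stats",
    "fit_ivw",
    "classic_for_design",
]

_Z95 = 1.959963984540054  # Normal 97.5% quantile


@dataclass
class ClassicEstimate:
    """Point estimates, standard errors and 95% Wald CIs for (b1, b2, b3)."""

    beta_hat: np.ndarray
    se: np.ndarray
    method: str  # "2SLS" or "IVW"

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float).reshape(3)
        self.se = np.asarray(self.se, dtype=float).reshape(3)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def ci95(self) -> np.ndarray:
        """(3, 2) array of beta_hat -/+ 1.96 se."""
        return np.column_stack([self.beta_hat - _Z95 * self.se, self.beta_hat + _Z95 * self.se])


@dataclass
class SummaryStats:
    """Two-sample MR summary statistics.

    ``gamma_hat[j, k]`` is the simple-regression slope of exposure
    X_{k+1} on instrument Z_{j+1} in the exposure-study rows, with
    ``gamma_se`` its standard error; ``Gamma_hat[j]`` is the slope of Y
    on Z_{j+1} in the outcome-study rows, with ``Gamma_se``.
    """

    gamma_hat: np.ndarray   # (3, 3)
    gamma_se: np.ndarray    # (3, 3)
    Gamma_hat: np.ndarray   # (3,)
    Gamma_se: np.ndarray    # (3,)

    def __post_init__(self) -> None:
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float).reshape(3, 3)
        self.gamma_se = np.asarray(self.gamma_se, dtype=float).reshape(3, 3)
        self.Gamma_hat = np.asarray(self.Gamma_hat, dtype=float).reshape(3)
        self.Gamma_se = np.asarray(self.Gamma_se, dtype=float).reshape(3)
        if np.any(self.gamma_se <= 0) or np.any(self.Gamma_se <= 0):
            raise ValueError("standard errors must be positive")


def fit_2sls(data: MRDataset) -> ClassicEstimate:
    """Multivariable 2SLS of Y on (X1, X2, X3) instrumented by (Z1, Z2, Z3).

    Requires complete rows (no missing cells).  Stage one projects each
    exposure on (1, Z); stage two regresses Y on (1, Xhat).  Standard
    errors are the classical homoskedastic form with residuals computed
    at the observed exposures.
    """
    if np.isnan(data.X).any() or np.isnan(data.Y).any():
        raise ValueError("2SLS requires a complete dataset (no missing cells)")
    n = data.n
    exog = np.column_stack([np.ones(n), data.X])
    instr = np.column_stack([np.ones(n), data.Z])
    if np.linalg.matrix_rank(instr) < instr.shape[1]:
        raise np.linalg.LinAlgError("first-stage design is rank deficient")
    res = IV2SLS(data.Y, exog, instrument=instr).fit()
    return ClassicEstimate(beta_hat=res.params[1:], se=res.bse[1:], method="2SLS")


def compute_summary_stats(B_rows: MRDataset, C_rows: MRDataset) -> SummaryStats:
    """Per-instrument association estimates for two-sample IVW.

    Simple linear regressions with intercept: X_k on Z_j in the
    exposure-study rows and Y on Z_j in the outcome-study rows.
    """
    X, Z_B = B_rows.X, B_rows.Z
    if np.isnan(X).any():
        raise ValueError("exposure-study rows must have observed X")
    yC = C_rows.Y
    if np.isnan(yC).any():
        raise ValueError("outcome-study rows must have observed Y")
    gamma = np.empty((3, 3))
    gamma_se = np.empty((3, 3))
    for j in range(3):
        z = Z_B[:, j]
        if np.var(z) == 0:
            raise ValueError(f"instrument Z{j + 1} has zero variance in the exposure study")
        for k in range(3):
            fit = stats.linregress(z, X[:, k])
            gamma[j, k] = fit.slope
            gamma_se[j, k] = fit.stderr
    Gamma = np.empty(3)
    Gamma_se = np.empty(3)
    for j in range(3):
        z = C_rows.Z[:, j]
        if np.var(z) == 0:
            raise ValueError(f"instrument Z{j + 1} has zero variance in the outcome study")
        fit = stats.linregress(z, yC)
        Gamma[j] = fit.slope
        Gamma_se[j] = fit.stderr
    return SummaryStats(gamma, gamma_se, Gamma, Gamma_se)


def fit_ivw(summary: SummaryStats) -> ClassicEstimate:
    """Multivariable fixed-effect IVW from summary statistics.

    Solves ``argmin sum_j w_j (Gamma_j - sum_k gamma_jk b_k)^2`` with
    ``w_j = Gamma_se_j^-2``; covariance ``(G' W G)^-1``.  With three
    instruments and three exposures the system is exactly identified and
    the point estimate reduces to gamma^-1 Gamma, independent of the
    weights.
    """
    G = summary.gamma_hat.reshape(3, 3)  # row j: instrument j's exposure associations
    w = 1.0 / summary.Gamma_se**2
    A = G.T @ (w[:, None] * G)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular instrument-exposure association matrix; instruments may be "
            "weak or collinear"
        ) from err
    if not np.all(np.isfinite(cov)) or np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError(
            "ill-conditioned instrument-exposure association matrix; instruments "
            "may be weak or collinear"
        )
    beta = cov @ (G.T @ (w * summary.Gamma_hat))
    se = np.sqrt(np.diag(cov))
    return ClassicEstimate(beta_hat=beta, se=se, method="IVW")


def classic_for_design(data: MRDataset) -> ClassicEstimate:
    """Design-appropriate classic estimator.

    100% overlap (all rows complete) -> 2SLS on everything; otherwise
    two-sample IVW on the non-overlapping rows only (group B for the
    exposure side, group C for the outcome side), discarding group A.
    """
    data.validate()
    n_B, n_C = data.n_B, data.n_C
    if n_B == 0 and n_C == 0:
        return fit_2sls(data)
    if n_B == 0 or n_C == 0:
        raise ValueError(
            "partially overlapping design needs non-empty groups B and C for IVW"
        )
    stats_ = compute_summary_stats(data.subset(data.mask("B")), data.subset(data.mask("C")))
    return fit_ivw(stats_)
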