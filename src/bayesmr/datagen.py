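"""Synthetic data for overlapping-sample Mendelian randomization studies.

The generative model is a linear structural equation system with three
genetic instruments ``Z = (Z1, Z2, Z3)``, three exposures
``X = (X1, X2, X3)``, a continuous outcome ``Y`` and a scalar latent
confounder ``U``::

    U  ~ N(0, 0.1)                                   (variance 0.1)
    X1 = w1 + a1*Z1          + d1*U + e1,   e1 ~ N(0, s1^2)
    X2 = w2 + a2*Z2          + d2*U + e2,   e2 ~ N(0, s2^2)
    X3 = w3 + a3*Z2 + a4*Z3  + d3*U + e3,   e3 ~ N(0, s3^2)
    Y  = wY + b1*X1 + b2*X2 + b3*X3 + d4*U + eY,  eY ~ N(0, sY^2)

Z2 loads on both X2 and X3 (horizontal pleiotropy), so there are four
instrument-strength parameters ``a1..a4`` even though there are only
three instruments.

A study design is produced by sampling three disjoint groups without
replacement from a fully observed population:

* group ``A`` — Z, X and Y all observed (the overlapping individuals),
* group ``B`` — Z and X observed, Y missing (exposure-study only),
* group ``C`` — Z and Y observed, X missing (outcome-study only).

``D1 = A + B`` and ``D2 = A + C`` are the instrument-exposure and
instrument-outcome association studies; the overlap rate is
``n_A / (n_A + n_B)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "U_VARIANCE",
    "SimulationConfig",
    "SplitSizes",
    "MRDataset",
    "compute_split_sizes",
    "generate_population",
    "split_into_ABC",
    "simulate_design",
    "write_dataset",
    "read_dataset",
]

#: Variance of the latent confounder U.  Fixed by the model, not estimated:
#: the confounder scale is carried by the delta coefficients.
U_VARIANCE = 0.1

#: Column order of the on-disk table.
_COLUMNS = ["Z1", "Z2", "Z3", "X1", "X2", "X3", "Y", "GROUP"]


def _as_vector(x, size: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(size, float(v))
    if v.shape != (size,):
        raise ValueError(f"{name} must be a scalar or length-{size} vector, got shape {v.shape}")
    return v


@dataclass
class SimulationConfig:
    """One cell of the simulation grid.

    Parameters
    ----------
    overlap_rate
        Fraction of each association study made up of fully observed
        (group-A) individuals.  The study grid uses
        {1.0, 0.8, 0.6, 0.4, 0.2, 0.0}; any fraction in [0, 1] is allowed.
    alpha_true
        Instrument strengths (a1, a2, a3, a4).  A scalar is broadcast.
    beta_true
        Causal effects (b1, b2, b3) of the exposures on the outcome.
    delta_true
        Confounding effects (d1, d2, d3, d4); d4 is the effect of U on Y.
    n_population
        Size of the fully observed population H from which groups are drawn.
    n_study
        Common size of the association studies D1 and D2.
    maf
        Minor-allele frequency used when instruments are SNP dosages.
    sigma_true
        True noise standard deviations (s1, s2, s3, sY).
    omega_true
        True intercepts (w1, w2, w3, wY).
    instrument_dist
        ``"binomial"`` for dosages Z ~ Binomial(2, maf) (default) or
        ``"normal"`` for Z ~ N(0, 1).
    u_sd
        Standard deviation of the generative confounder U.  The default
        0.1 is calibrated so that the closed-form 2SLS sampling sd at
        n_study=400 with strong instruments is ~0.02, the precision
        scale of the classic comparator this package reproduces.  (The
        *fitted* model's U prior has variance 0.1 regardless; its scale
        is absorbed by the delta coefficients.)
    seed
        Seed for population generation.
    """

    overlap_rate: float = 1.0
    alpha_true: np.ndarray = 0.5
    beta_true: np.ndarray = 0.3
    delta_true: np.ndarray = 1.0
    n_population: int = 1000
    n_study: int = 400
    maf: float = 0.3
    sigma_true: np.ndarray = 0.1
    omega_true: np.ndarray = 0.0
    instrument_dist: str = "binomial"
    u_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha_true = _as_vector(self.alpha_true, 4, "alpha_true")
        self.beta_true = _as_vector(self.beta_true, 3, "beta_true")
        self.delta_true = _as_vector(self.delta_true, 4, "delta_true")
        self.sigma_true = _as_vector(self.sigma_true, 4, "sigma_true")
        self.omega_true = _as_vector(self.omega_true, 4, "omega_true")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ValueError(f"overlap_rate must be in [0, 1], got {self.overlap_rate}")
        if self.n_study <= 0 or self.n_population <= 0:
            raise ValueError("n_study and n_population must be positive")
        if self.n_study > self.n_population:
            raise ValueError("n_study cannot exceed n_population")
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"maf must be in (0, 1), got {self.maf}")
        if np.any(self.sigma_true <= 0):
            raise ValueError("all sigma_true must be positive")
        if self.u_sd <= 0:
            raise ValueError("u_sd must be positive")
        if self.instrument_dist not in ("binomial", "normal"):
            raise ValueError(f"unknown instrument_dist {self.instrument_dist!r}")

    def split_sizes(self) -> "SplitSizes":
        return compute_split_sizes(self.overlap_rate, self.n_study)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SplitSizes:
    """Group sizes of a design: n_A + n_B = n_study and n_B = n_C."""

    n_A: int
    n_B: int
    n_C: int

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B, self.n_C) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_B != self.n_C:
            raise ValueError("n_B and n_C must be equal")

    @property
    def total(self) -> int:
        return self.n_A + self.n_B + self.n_C


def compute_split_sizes(overlap_rate: float, n_study: int) -> SplitSizes:
    """Group sizes implied by an overlap rate.

    ``n_A = round(overlap_rate * n_study)`` (round half to even) and
    ``n_B = n_C = n_study - n_A``.  E.g. an 80% overlap at n_study=400
    gives n_A=320 and n_B=n_C=80.
    """
    if not 0.0 <= overlap_rate <= 1.0:
        raise ValueError(f"overlap_rate must be in [0, 1], got {overlap_rate}")
    if n_study <= 0:
        raise ValueError(f"n_study must be positive, got {n_study}")
    n_A = int(np.round(overlap_rate * n_study))
    return SplitSizes(n_A=n_A, n_B=n_study - n_A, n_C=n_study - n_A)


@dataclass
class MRDataset:
    """Individual-level data with explicit missingness.

    ``Z`` is an (n, 3) instrument matrix (never missing); ``X`` is an
    (n, 3) exposure matrix and ``Y`` an (n,) outcome vector, both using
    NaN for missing cells; ``group`` is an (n,) array of labels in
    {"A", "B", "C"}.  Group A rows are complete, group B rows have Y
    missing, group C rows have X missing.
    """

    Z: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        n = self.Z.shape[0]
        if self.Z.shape != (n, 3) or self.X.shape != (n, 3):
            raise ValueError("Z and X must have shape (n, 3)")
        if self.Y.shape != (n,) or self.group.shape != (n,):
            raise ValueError("Y and group must have shape (n,)")

    # -- group views ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def mask(self, label: str) -> np.ndarray:
        return self.group == label

    @property
    def n_A(self) -> int:
        return int(np.sum(self.group == "A"))

    @property
    def n_B(self) -> int:
        return int(np.sum(self.group == "B"))

    @property
    def n_C(self) -> int:
        return int(np.sum(self.group == "C"))

    def split_sizes(self) -> SplitSizes:
        return SplitSizes(self.n_A, self.n_B, self.n_C)

    def validate(self) -> None:
        """Check the group/missingness contract; raise ValueError on breach."""
        bad = set(np.unique(self.group)) - {"A", "B", "C"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if np.isnan(self.Z).any():
            raise ValueError("Z must be fully observed")
        for label, x_missing, y_missing in (
            ("A", False, False),
            ("B", False, True),
            ("C", True, False),
        ):
            rows = self.mask(label)
            if not rows.any():
                continue
            x_nan = np.isnan(self.X[rows])
            y_nan = np.isnan(self.Y[rows])
            if x_missing and not x_nan.all():
                raise ValueError(f"group {label} rows must have all X missing")
            if not x_missing and x_nan.any():
                raise ValueError(f"group {label} rows must have all X observed")
            if y_missing and not y_nan.all():
                raise ValueError(f"group {label} rows must have Y missing")
            if not y_missing and y_nan.any():
                raise ValueError(f"group {label} rows must have Y observed")

    def subset(self, rows: np.ndarray) -> "MRDataset":
        return MRDataset(self.Z[rows], self.X[rows], self.Y[rows], self.group[rows])

    # -- tabular form ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.column_stack([self.Z, self.X, self.Y[:, None]]),
            columns=_COLUMNS[:-1],
        )
        df["GROUP"] = self.group
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MRDataset":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        data = cls(
            Z=df[["Z1", "Z2", "Z3"]].to_numpy(dtype=float),
            X=df[["X1", "X2", "X3"]].to_numpy(dtype=float),
            Y=df["Y"].to_numpy(dtype=float),
            group=df["GROUP"].to_numpy(dtype=object),
        )
        data.validate()
        return data


def generate_population(config: SimulationConfig) -> MRDataset:
    """Draw a fully observed population H of ``config.n_population`` rows.

    Instruments are independent across columns and individuals; U and the
    noise terms are independent normals.  All rows are labelled "A"
    (complete).  Reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_population
    if config.instrument_dist == "binomial":
        Z = rng.binomial(2, config.maf, size=(n, 3)).astype(float)
    else:
        Z = rng.standard_normal((n, 3))
    U = rng.normal(0.0, config.u_sd, size=n)
    w, a, d, b, s = (
        config.omega_true,
        config.alpha_true,
        config.delta_true,
        config.beta_true,
        config.sigma_true,
    )
    X = np.empty((n, 3))
    X[:, 0] = w[0] + a[0] * Z[:, 0] + d[0] * U + rng.normal(0.0, s[0], n)
    X[:, 1] = w[1] + a[1] * Z[:, 1] + d[1] * U + rng.normal(0.0, s[1], n)
    X[:, 2] = w[2] + a[2] * Z[:, 1] + a[3] * Z[:, 2] + d[2] * U + rng.normal(0.0, s[2], n)
    Y = w[3] + X @ b + d[3] * U + rng.normal(0.0, s[3], n)
    return MRDataset(Z=Z, X=X, Y=Y, group=np.full(n, "A", dtype=object))


def split_into_ABC(H: MRDataset, sizes: SplitSizes, seed: int) -> MRDataset:
    """Carve disjoint groups A, B, C out of a population, without replacement.

    Group A keeps (Z, X, Y); group B keeps (Z, X) and masks Y; group C
    keeps (Z, Y) and masks X.  Unsampled rows are discarded.  Rows are
    returned in A, B, C order.
    """
    if sizes.total > H.n:
        raise ValueError(
            f"requested {sizes.total} rows but population has only {H.n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(H.n, size=sizes.total, replace=False)
    out = H.subset(chosen)
    group = np.concatenate(
        [
            np.full(sizes.n_A, "A", dtype=object),
            np.full(sizes.n_B, "B", dtype=object),
            np.full(sizes.n_C, "C", dtype=object),
        ]
    )
    Y = out.Y.copy()
    X = out.X.copy()
    Y[group == "B"] = np.nan
    X[group == "C"] = np.nan
    result = MRDataset(Z=out.Z, X=X, Y=Y, group=group)
    result.validate()
    return result


def simulate_design(config: SimulationConfig) -> MRDataset:
    """Generate a population and split it per ``config.overlap_rate``."""
    H = generate_population(config)
    # independent stream for the subsampling step
    return split_into_ABC(H, config.split_sizes(), seed=np.random.default_rng([config.seed, 1]).integers(2**31))


def write_dataset(data: MRDataset, path) -> None:
    """Write a dataset as a TSV with header and literal "NA" for missing."""
    data.validate()
    data.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dataset(path) -> MRDataset:
    """Read a TSV written by :func:`write_dataset`; validates the contract."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in _COLUMNS[:-1]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = coerced
    return MRDataset.from_frame(df)
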