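"""Simulation-study harness.

Runs a grid of simulation configurations — overlap rate x instrument
strength x confounding level x causal-effect level — with many
replicates per cell, fits the Bayesian model and the design-appropriate
classic estimator on each replicate, and aggregates four metrics per
exposure and method:

* ``mean`` and ``sd``: average and standard deviation (n-1 denominator)
  of the point estimates across replicates,
* ``coverage``: fraction of replicates whose 95% interval contains the
  true causal effect,
* ``power``: fraction of replicates whose 95% interval excludes zero
  (defined only when the true effect is non-zero).

The full study grid is 6 overlap rates x 2 instrument strengths x 3
confounding levels x 2 effect levels = 72 configurations at 200
replicates each; ``n_replicates`` can be reduced for desk-scale runs.
The confounder-on-outcome effect d4 is fixed at 1 in every cell.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classic import classic_for_design
from .datagen import SimulationConfig, simulate_design
from .model_core import PriorSpec
from .sampler import SamplerConfig, run_chain

__all__ = [
    "GridSpec",
    "MetricRow",
    "replicate_seed",
    "run_replicate",
    "aggregate",
    "run_grid",
    "write_tables",
]

logger = logging.getLogger(__name__)

#: Effect of the confounder on the outcome, fixed across the grid.
DELTA4 = 1.0


@dataclass(frozen=True)
class GridSpec:
    """The simulation grid (defaults give the full 72-cell study)."""

    overlap_rates: tuple = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)
    alpha_levels: tuple = (0.5, 0.1)
    delta_levels: tuple = (1.0, 0.5, 0.1)
    beta_levels: tuple = (0.3, 0.0)
    n_replicates: int = 200
    base_seed: int = 0

    @property
    def n_configurations(self) -> int:
        return (
            len(self.overlap_rates) * len(self.alpha_levels)
            * len(self.delta_levels) * len(self.beta_levels)
        )

    def configurations(self):
        """Yield (index, overlap, alpha, delta, beta) cells in grid order."""
        cells = itertools.product(
            self.overlap_rates, self.alpha_levels, self.delta_levels, self.beta_levels
        )
        for i, (rate, a, d, b) in enumerate(cells):
            yield i, rate, a, d, b

    def simulation_config(self, rate, alpha, delta, beta, seed=0, **kwargs) -> SimulationConfig:
        """Build the per-cell generative configuration (d4 = 1)."""
        return SimulationConfig(
            overlap_rate=rate,
            alpha_true=np.full(4, alpha),
            beta_true=np.full(3, beta),
            delta_true=np.array([delta, delta, delta, DELTA4]),
            seed=seed,
            **kwargs,
        )


@dataclass
class MetricRow:
    """One aggregated cell: a (configuration, exposure, method) triple."""

    overlap_rate: float
    alpha_level: float
    delta_level: float
    beta_truth: float
    exposure: int          # 1-based exposure index
    method: str            # "Bayesian" or "Classic"
    estimator: str         # "Bayesian", "2SLS" or "IVW"
    n_replicates: int
    mean: float
    sd: float
    coverage: float
    power: float           # NaN when beta_truth == 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if np.isfinite(self.power) and not 0.0 <= self.power <= 1.0:
            raise ValueError("power must be in [0, 1]")


def replicate_seed(base_seed: int, config_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed, re-runnable in isolation."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(config_index, replicate_index))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


def run_replicate(
    config: SimulationConfig,
    sampler_config: SamplerConfig,
    seed: int,
    priors: PriorSpec | None = None,
):
    """Simulate one dataset and fit both methods.

    Returns a list of records, one per (method, exposure), each with the
    point estimate and 95% interval.  Fully reproducible from ``seed``.
    """
    priors = priors or PriorSpec()
    data_seed, mcmc_seed = (
        int(s % np.uint32(2**31))
        for s in np.random.SeedSequence(seed).generate_state(2)
    )
    data = simulate_design(config.replace(seed=data_seed))

    records = []
    summary = run_chain(
        data, priors, SamplerConfig(**{**sampler_config.__dict__, "seed": mcmc_seed})
    )
    b_mean, b_ci = summary.beta_estimates()
    for k in range(3):
        records.append(
            dict(method="Bayesian", estimator="Bayesian", exposure=k + 1,
                 estimate=float(b_mean[k]), lo=float(b_ci[k, 0]), hi=float(b_ci[k, 1]))
        )
    classic = classic_for_design(data)
    for k in range(3):
        records.append(
            dict(method="Classic", estimator=classic.method, exposure=k + 1,
                 estimate=float(classic.beta_hat[k]),
                 lo=float(classic.ci95[k, 0]), hi=float(classic.ci95[k, 1]))
        )
    return records


def aggregate(replicate_records, truth: float):
    """Aggregate replicate-level records into per-(method, exposure) metrics.

    ``replicate_records`` is an iterable of record lists as returned by
    :func:`run_replicate`.  Raises if there are no successful replicates.
    """
    flat = [r for records in replicate_records for r in records]
    if not flat:
        raise ValueError("no successful replicates to aggregate")
    df = pd.DataFrame(flat)
    out = []
    for (method, estimator, exposure), g in df.groupby(["method", "estimator", "exposure"]):
        est = g["estimate"].to_numpy()
        covered = (g["lo"] <= truth) & (truth <= g["hi"])
        if truth != 0.0:
            power = float(np.mean((g["lo"] > 0.0) | (g["hi"] < 0.0)))
        else:
            power = np.nan
        out.append(
            dict(method=method, estimator=estimator, exposure=int(exposure),
                 n_replicates=len(g), mean=float(est.mean()),
                 sd=float(est.std(ddof=1)) if len(est) > 1 else np.nan,
                 coverage=float(covered.mean()), power=power)
        )
    return out


def _safe_replicate(config, sampler_config, seed, priors):
    """run_replicate wrapper that records failures instead of raising."""
    try:
        return run_replicate(config, sampler_config, seed, priors), None
    except Exception as err:  # failure policy: record and exclude
        return None, f"{type(err).__name__}: {err}"


def run_grid(
    grid: GridSpec,
    sampler_config: SamplerConfig | None = None,
    priors: PriorSpec | None = None,
    sim_kwargs: dict | None = None,
    out_dir=None,
    keep_replicates: bool = False,
    n_jobs: int = 1,
):
    """Run every cell of the grid and aggregate the metrics.

    Returns a metrics DataFrame with one row per (configuration,
    exposure, method).  When ``out_dir`` is given, writes ``table1.csv``
    (non-zero effects, with power), ``table2.csv`` (null effects) and
    ``replicates.csv`` there.  Failed replicates are logged and excluded
    from the metrics, with their count recorded per cell.
    """
    sampler_config = sampler_config or SamplerConfig()
    priors = priors or PriorSpec()
    sim_kwargs = sim_kwargs or {}
    metric_rows = []
    replicate_rows = []
    t0 = time.monotonic()
    for index, rate, alpha, delta, beta in grid.configurations():
        config = grid.simulation_config(rate, alpha, delta, beta, **sim_kwargs)
        seeds = [replicate_seed(grid.base_seed, index, rep) for rep in range(grid.n_replicates)]
        if n_jobs == 1:
            raw = [_safe_replicate(config, sampler_config, s, priors) for s in seeds]
        else:
            from joblib import Parallel, delayed

            raw = Parallel(n_jobs=n_jobs)(
                delayed(_safe_replicate)(config, sampler_config, s, priors) for s in seeds
            )
        results, n_failed = [], 0
        for rep, (records, error) in enumerate(raw):
            if error is not None:
                n_failed += 1
                logger.error(
                    "replicate %d of configuration %d failed (seed %d): %s",
                    rep, index, seeds[rep], error,
                )
                continue
            results.append(records)
            if keep_replicates:
                for r in records:
                    replicate_rows.append(
                        dict(config_index=index, replicate=rep, seed=seeds[rep],
                             overlap_rate=rate, alpha_level=alpha,
                             delta_level=delta, beta_truth=beta, **r)
                    )
        if n_failed:
            logger.warning("configuration %d: %d failed replicate(s)", index, n_failed)
        for agg in aggregate(results, truth=beta):
            metric_rows.append(
                dict(overlap_rate=rate, alpha_level=alpha, delta_level=delta,
                     beta_truth=beta, n_failed=n_failed, **agg)
            )
        logger.info(
            "configuration %d/%d done (overlap=%.0f%%, alpha=%g, delta=%g, beta=%g) "
            "[%.1fs elapsed]",
            index + 1, grid.n_configurations, 100 * rate, alpha, delta, beta,
            time.monotonic() - t0,
        )
    metrics = pd.DataFrame(metric_rows)
    if out_dir is not None:
        write_tables(metrics, out_dir)
        if keep_replicates:
            pd.DataFrame(replicate_rows).to_csv(Path(out_dir) / "replicates.csv", index=False)
    return metrics


def write_tables(metrics: pd.DataFrame, out_dir) -> None:
    """Write table1.csv (non-null effects, with power) and table2.csv
    (null effects, no power column) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alt = metrics[metrics["beta_truth"] != 0.0]
    null = metrics[metrics["beta_truth"] == 0.0].drop(columns=["power"], errors="ignore")
    alt.to_csv(out / "table1.csv", index=False)
    null.to_csv(out / "table2.csv", index=False)


def plot_metric(metrics: pd.DataFrame, metric: str, path=None):
    """Bar chart of one metric by overlap rate, per exposure and method.

    A thin convenience layer over the metrics table; the numbers, not
    the figures, are the replication output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for k, ax in enumerate(axes):
        sub = metrics[metrics["exposure"] == k + 1]
        for method, g in sub.groupby("method"):
            g = g.sort_values("overlap_rate")
            ax.plot(g["overlap_rate"], g[metric], marker="o", label=method)
        ax.set_title(f"exposure {k + 1}")
        ax.set_xlabel("overlap rate")
    axes[0].set_ylabel(metric)
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
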