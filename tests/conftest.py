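import numpy as np
import pytest

from bayesmr import MRDataset, PriorSpec, SamplerConfig, SimulationConfig, simulate_design


@pytest.fixture(scope="session")
def priors():
    return PriorSpec()


@pytest.fixture(scope="session")
def fast_sampler():
    """Short chain for smoke-scale fits."""
    return SamplerConfig(n_iter=300, n_warmup=100, seed=0)


@pytest.fixture(scope="session")
def complete_data():
    """Small fully observed (one-sample) dataset."""
    cfg = SimulationConfig(overlap_rate=1.0, n_population=200, n_study=80, seed=42)
    return simulate_design(cfg)


@pytest.fixture(scope="session")
def overlap_data():
    """80%-overlap design at the study scale (320/80/80)."""
    cfg = SimulationConfig(overlap_rate=0.8, seed=7)
    return simulate_design(cfg)


def make_abc_dataset(n_A=4, n_B=3, n_C=2, seed=0):
    """Tiny A/B/C dataset with the missingness contract satisfied."""
    rng = np.random.default_rng(seed)
    n = n_A + n_B + n_C
    Z = rng.binomial(2, 0.4, (n, 3)).astype(float)
    X = rng.normal(size=(n, 3))
    Y = rng.normal(size=n)
    group = np.array(["A"] * n_A + ["B"] * n_B + ["C"] * n_C, dtype=object)
    X[group == "C"] = np.nan
    Y[group == "B"] = np.nan
    data = MRDataset(Z, X, Y, group)
    data.validate()
    return data
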