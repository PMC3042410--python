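import numpy as np
import pandas as pd
import pytest

from polyte.normalize import ExpressionMatrix
from polyte.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast, noisy study: 150 genes, defaults otherwise."""
    return SimulationConfig(n_genes=150, probes_per_gene=3, seed=11)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(
        n_genes=120,
        probes_per_gene=3,
        sigma_bio=0.0,
        sigma_tech=0.0,
        sigma_probe=0.3,  # probe affinities cancel in summarization
        sigma_scale=0.0,
        sigma_ct=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return simulate_dataset(noise_free_config)


def toy_summarized(te_wt, te_mut, abundance=None, projects=("I", "II", "III")):
    """Build a linear-scale group-summarized matrix with exact per-project
    TEs (same value each project unless 2-D arrays are given)."""
    te_wt = np.atleast_2d(np.asarray(te_wt, dtype=float))
    te_mut = np.atleast_2d(np.asarray(te_mut, dtype=float))
    if te_wt.shape[0] == 1:
        te_wt = np.repeat(te_wt, len(projects), axis=0)
        te_mut = np.repeat(te_mut, len(projects), axis=0)
    n = te_wt.shape[1]
    if abundance is None:
        abundance = np.full(n, 100.0)
    cols = {}
    for k, proj in enumerate(projects):
        cols[("WT", "T", proj)] = abundance
        cols[("WT", "HP", proj)] = abundance * te_wt[k]
        cols[("mutant", "T", proj)] = abundance
        cols[("mutant", "HP", proj)] = abundance * te_mut[k]
    df = pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["strain", "fraction", "project"])
    return ExpressionMatrix(df, scale="linear")
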