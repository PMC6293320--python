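import numpy as np
import pandas as pd
import pytest

import coexpair as cx


SMALL_CONFIG = dict(
    n_genes=600,
    n_cases=100,
    n_controls=100,
    n_modules=3,
    module_sizes=(100, 80, 60),
    n_snps=60,
    seed=42,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact paired-condition dataset shared across tests."""
    return cx.simulate_dataset(cx.SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def detected(small_dataset):
    """Baseline network, dissimilarity, and detected modules for the small dataset."""
    ds = small_dataset
    adj = cx.adjacency(ds.expr_base, 4)
    dt = cx.network.dist_tom(cx.tom(adj))
    dend = cx.average_linkage(dt)
    raw = cx.cut_tree_dynamic(dend, min_size=50, cut_height=0.99)
    assign, me = cx.merge_close_modules(ds.expr_base, raw)
    return dict(adj=adj, dist_tom=dt, dendrogram=dend, assign=assign, me=me)


def factor_expression(n_genes, n_samples, loading=1.0, noise_sd=0.5, seed=0,
                      prefix="G"):
    """One-factor expression block with constant loading; returns (matrix, factor)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_samples)
    x = loading * u + rng.normal(scale=noise_sd, size=(n_genes, n_samples))
    m = pd.DataFrame(
        x,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return m, u
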