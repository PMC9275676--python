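import numpy as np
import pandas as pd
import pytest

from chromshift import simulate
from chromshift.chipnorm import CountMatrix


@pytest.fixture(scope="session")
def two_chrom_genome():
    return simulate.simulate_genome(n_chroms=2, chrom_length=500_000, n_genes=50, seed=1)


def nb_count_matrix(seed, nfeat=200, n_per_group=2, baseline=200.0, dispersion=0.05, lfc=None):
    """Negative-binomial count matrix helper shared across tests."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(baseline), 0.8, nfeat)
    lfc = np.zeros(nfeat) if lfc is None else lfc
    cols = {}
    for i in range(n_per_group):
        cols[f"A{i}"] = rng.poisson(rng.gamma(1 / dispersion, base * dispersion))
    for i in range(n_per_group):
        mu = base * 2.0**lfc
        cols[f"B{i}"] = rng.poisson(rng.gamma(1 / dispersion, mu * dispersion))
    counts = pd.DataFrame(cols, index=[f"f{i:05d}" for i in range(nfeat)])
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(500, index=counts.index),
        library_sizes=counts.sum(axis=0),
        conditions=pd.Series(
            ["A"] * n_per_group + ["B"] * n_per_group, index=counts.columns
        ),
    )
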