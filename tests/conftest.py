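import numpy as np
import pandas as pd
import pytest

from bvsgwas.data import GeneticMap, GenotypeMatrix


def make_genotypes(codes, pos=None, chrom=None, **kwargs) -> GenotypeMatrix:
    """GenotypeMatrix with a trivial single-chromosome map."""
    codes = np.asarray(codes, dtype=np.int8)
    m = codes.shape[1]
    if pos is None:
        pos = (np.arange(m) + 0.5) / max(m, 1)
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    return GenotypeMatrix(codes, GeneticMap(np.asarray(chrom), np.asarray(pos)), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_sim():
    """One desk-scale simulated dataset, shared across tests."""
    from bvsgwas.simulate import simulate_population

    return simulate_population(seed=1, desk=True)


@pytest.fixture(scope="session")
def desk_fit(desk_sim):
    """Full-model fit of the shared desk dataset (10k cycles)."""
    from bvsgwas.model import BayesianVariableSelection

    model = BayesianVariableSelection.from_simulation(desk_sim)
    return model.fit(n_cycles=10_000, burn_in=2_000, thin=10, seed=1)


def no_phenotype_series(ids):
    return pd.Series(np.nan, index=list(ids), name="phenotype")
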