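import numpy as np
import pandas as pd
import pytest

from synores import SimulationConfig, simulate_cohort, vst_transform


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 300-gene three-arm cohort with default signal."""
    cfg = SimulationConfig(n_samples=60, n_genes=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_vst(small_cohort):
    counts, _, _ = small_cohort
    return vst_transform(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_counts(matrix, genes=None, samples=None):
    """Small helper: wrap a plain array as a GeneCountMatrix."""
    from synores import GeneCountMatrix

    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return GeneCountMatrix(pd.DataFrame(matrix, index=genes, columns=samples))
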