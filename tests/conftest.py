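import numpy as np
import pandas as pd
import pytest

from periput import genesets, simulate


@pytest.fixture(scope="session")
def put_sets() -> genesets.GeneSetCollection:
    return genesets.builtin_put_genesets()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort reused by several module tests."""
    cfg = simulate.SimConfig(n_samples=8, cells_per_sample=150, seed=11)
    counts, ann, truth = simulate.simulate_sc_cohort(cfg)
    return cfg, counts, ann, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_expression(rng: np.random.Generator, n_genes: int, n_units: int) -> pd.DataFrame:
    values = rng.normal(size=(n_genes, n_units))
    return pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"U{j}" for j in range(n_units)],
    )
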