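"""Shared fixtures: small deterministic datasets built in memory."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cider.core import CellMeta, CountMatrix, ExpressionMatrix, lognormalize
from cider.simulate import SimConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """60 cells x 50 genes of sparse Poisson counts, two batches."""
    counts = rng.poisson(1.2, size=(60, 50))
    cm = CountMatrix(sp.csr_matrix(counts),
                     [f"c{i}" for i in range(60)],
                     [f"g{j}" for j in range(50)])
    meta = CellMeta(pd.DataFrame(
        {"batch": ["b1"] * 30 + ["b2"] * 30}, index=cm.cell_ids))
    return cm, meta


@pytest.fixture(scope="session")
def sim_two_pop():
    """Two populations in two batches with batch effects; plus truth."""
    cfg = SimConfig(
        composition={"b1": {"popA": 120, "popB": 120},
                     "b2": {"popA": 120, "popB": 120}},
        n_genes=600, de_prob=0.1, de_sigma=2.0, batch_sigma=0.5, seed=77)
    cm, meta, truth = simulate_counts(cfg)
    em = lognormalize(cm)
    return em, meta, truth


@pytest.fixture
def dense_positive_em(rng):
    """Strictly positive dense expression: detection pattern is shift-proof."""
    vals = rng.lognormal(0.5, 0.4, size=(120, 80))
    em = ExpressionMatrix(vals, [f"c{i}" for i in range(120)],
                          [f"g{j}" for j in range(80)])
    meta = CellMeta(pd.DataFrame(
        {"batch": ["b1"] * 60 + ["b2"] * 60}, index=em.cell_ids))
    return em, meta
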