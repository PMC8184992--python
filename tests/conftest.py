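import numpy as np
import pandas as pd
import pytest

from aseqcc.counts import GENE_COL, MAT_COL, PAT_COL


def make_table(maternal, paternal, gene_ids=None) -> pd.DataFrame:
    maternal = np.asarray(maternal, dtype=np.int64)
    paternal = np.asarray(paternal, dtype=np.int64)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(maternal))]
    return pd.DataFrame({GENE_COL: gene_ids, MAT_COL: maternal, PAT_COL: paternal})


@pytest.fixture
def small_table():
    return make_table([5, 0, 30], [5, 50, 70])


@pytest.fixture
def binomial_pair():
    """Two replicate tables from pure binomial sampling (no overdispersion)."""
    rng = np.random.default_rng(1234)
    n = 4000
    cov = np.exp(rng.uniform(np.log(50), np.log(5000), n)).astype(int)
    p = np.where(rng.random(n) < 0.7, rng.beta(10, 10, n), rng.beta(0.2, 0.2, n))
    reps = []
    for _ in range(2):
        m = rng.binomial(cov, p)
        reps.append(make_table(m, cov - m))
    return reps[0], reps[1]
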