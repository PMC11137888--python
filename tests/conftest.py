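import numpy as np
import pandas as pd
import pytest

from refstab.core import CtMatrix


def make_ct(values, genes=None, samples=None, groups=None) -> CtMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=genes, columns=samples), groups)


def random_ct(rng, n_genes, n_samples, low=18.0, high=30.0) -> CtMatrix:
    values = rng.uniform(low, high, size=(n_genes, n_samples))
    return make_ct(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240530)


@pytest.fixture
def three_gene_ct():
    """Hand-checked 3x3 matrix used by the Delta Ct / geNorm oracles."""
    return make_ct([[20, 21, 22], [25, 26, 27], [30, 30, 31]],
                   genes=["A", "B", "C"])
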