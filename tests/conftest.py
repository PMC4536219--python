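import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_incidence(rng, n_sites, n_taxa, p=0.4, ensure_valid=True):
    """Random binary matrix; optionally resampled until RA-analysable
    (no empty rows/columns)."""
    while True:
        A = (rng.random((n_sites, n_taxa)) < p).astype(np.int64)
        if not ensure_valid or (A.sum(axis=0).min() > 0 and A.sum(axis=1).min() > 0):
            return A


@pytest.fixture
def small_abundance():
    return pd.DataFrame(
        [[3, 0, 1, 0], [0, 2, 0, 0], [5, 1, 2, 0], [0, 0, 4, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def banded_incidence():
    """Perfectly banded (staircase) 6x6 matrix: fully coherent."""
    A = np.zeros((6, 6), dtype=np.int64)
    for j in range(6):
        A[j : j + 2, j] = 1
    A[5, 5] = 1
    return pd.DataFrame(
        A, index=[f"s{i}" for i in range(6)], columns=[f"t{j}" for j in range(6)]
    )
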