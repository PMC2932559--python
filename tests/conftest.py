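import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from finescale.otu_io import CountTable

settings.register_profile("det", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("det")


@pytest.fixture
def toy_table():
    """Two samples, three OTUs: one shared, one unique to each sample."""
    df = pd.DataFrame({"s1": [2, 1, 0], "s2": [0, 1, 3]}, index=["o1", "o2", "o3"])
    return CountTable(df)


@pytest.fixture
def quad_table():
    """Four-sample table with a shared core and partially private tails."""
    rng = np.random.default_rng(7)
    core = rng.integers(20, 200, size=(30, 4))
    tail = rng.integers(0, 4, size=(120, 4))
    counts = np.vstack([core, tail])
    df = pd.DataFrame(counts, index=[f"OTU{i:04d}" for i in range(len(counts))],
                      columns=["q1", "q2", "q3", "q4"])
    return CountTable(df, drop_empty=True)


def random_table(rng: np.random.Generator, n_otus: int = 25, n_samples: int = 3,
                 max_count: int = 8) -> CountTable:
    """Small random count table with non-empty rows and columns."""
    counts = rng.integers(0, max_count + 1, size=(n_otus, n_samples))
    counts[rng.integers(0, n_otus), :] += 1          # no empty columns
    counts = counts[counts.sum(axis=1) > 0]
    df = pd.DataFrame(counts, index=[f"OTU{i}" for i in range(len(counts))],
                      columns=[f"s{j}" for j in range(n_samples)])
    return CountTable(df)
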