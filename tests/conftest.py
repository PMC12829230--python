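import numpy as np
import pandas as pd
import pytest

from gbsmedip.counting import CountMatrix
from gbsmedip.simulate import build_design, simulate_counts


@pytest.fixture
def two_group_design():
    samples = [f"s{i}" for i in range(1, 7)]
    return pd.Series(["a"] * 3 + ["b"] * 3, index=samples)


@pytest.fixture
def ten_sample_design():
    samples = [f"s{i}" for i in range(1, 11)]
    return pd.Series(["a"] * 5 + ["b"] * 5, index=samples)


@pytest.fixture
def small_counts(two_group_design):
    """8 windows x 6 samples integer fixture with mixed magnitudes and zeros."""
    rng = np.random.default_rng(7)
    mat = rng.negative_binomial(2, 0.15, size=(8, 6))
    mat[0, 0] = 0
    df = pd.DataFrame(
        mat, index=[f"w{i}" for i in range(8)], columns=two_group_design.index
    )
    return CountMatrix(df, design=two_group_design)


@pytest.fixture
def fragment_table():
    """20 read pairs: 15 eligible, 3 at/below the MAPQ cutoff, 2 discordant."""
    rows = []
    for i in range(15):
        rows.append(("chr1", 1000 + 500 * i, 1180 + 500 * i, 42, True, "s1"))
    rows.append(("chr1", 100, 250, 10, True, "s1"))  # mapq == cutoff: excluded
    rows.append(("chr1", 300, 450, 3, True, "s1"))
    rows.append(("chr2", 100, 260, 9, True, "s2"))
    rows.append(("chr2", 500, 700, 42, False, "s2"))  # discordant
    rows.append(("chr2", 900, 1100, 42, False, "s2"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mapq", "proper_pair", "sample_id"]
    )


@pytest.fixture(scope="session")
def default_sim():
    """One seeded draw of the full benchmark simulation (shared across tests)."""
    design = build_design(seed=11)
    cm, truth = simulate_counts(design, seed=11)
    return design, cm, truth
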