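import numpy as np
import pandas as pd
import pytest

from felicore.table_io import CountTable, RelAbundTable, to_relative_abundance


@pytest.fixture
def small_counts() -> CountTable:
    """3 taxa x 4 samples with one low-depth sample (s4)."""
    df = pd.DataFrame(
        {
            "s1": [4000, 2500, 600],
            "s2": [3000, 1980, 20],
            "s3": [5200, 100, 24],
            "s4": [3000, 1000, 999],
        },
        index=pd.Index(["Bacteroides", "Blautia", "Slackia"], name="taxon_id"),
    )
    return CountTable(df)


@pytest.fixture
def rel_table(small_counts) -> RelAbundTable:
    return to_relative_abundance(small_counts)


def random_count_table(rng: np.random.Generator, n_taxa=6, n_samples=5) -> CountTable:
    counts = rng.integers(0, 2000, size=(n_taxa, n_samples))
    counts[:, counts.sum(axis=0) == 0] += 1
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(n_taxa)], name="taxon_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CountTable(df)


def manual_percentile(sorted_vals, q_pct: float) -> float:
    """Linear-interpolation percentile written out by hand (oracle).

    h = (n - 1) * q; value = v[floor(h)] + frac(h) * (v[floor(h)+1] - v[floor(h)])
    """
    v = list(sorted_vals)
    n = len(v)
    if n == 1:
        return float(v[0])
    h = (n - 1) * (q_pct / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return float(v[lo] + frac * (v[hi] - v[lo]))
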