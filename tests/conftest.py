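import numpy as np
import pytest
from hypothesis import settings

from neutrochi import CountTable, brca2_counts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def brca2_table() -> CountTable:
    return brca2_counts()


@pytest.fixture
def brca2_csv(tmp_path):
    """The BRCA2 table written as CSV with thousands separators, as a
    published table would be pasted."""
    path = tmp_path / "brca2.csv"
    path.write_text(
        ",A,C,G,T\n"
        'Count Group 1,"38,514","24,631","25,685","38,249"\n'
        'Count Group 2,"38,550","24,635","25,700","38,288"\n'
    )
    return path


def random_count_table(rng: np.random.Generator, h=None, k=None, max_count=200):
    """A random valid count table for property-style checks."""
    h = h or int(rng.integers(1, 5))
    k = k or int(rng.integers(2, 6))
    counts = rng.integers(0, max_count, size=(h, k))
    # guarantee every category has a positive pooled total
    counts[0, :] += 1
    return CountTable(
        tuple(f"g{j}" for j in range(h)),
        tuple(f"c{i}" for i in range(k)),
        counts,
    )
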