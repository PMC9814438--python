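import numpy as np
import pytest

from greyzone import from_counts

# Torture-allegation assessment: two raters scoring the level of detail in
# descriptions of physical symptoms on a 0-3 ordinal scale, n = 202 cases.
TORTURE_COUNTS = [
    [36, 0, 0, 0],
    [7, 57, 11, 0],
    [0, 23, 34, 4],
    [0, 1, 19, 10],
]

# The same table with the grey-zone counts moved back to the diagonal:
# a no-grey-zone control with the same subjects.
TORTURE_NO_GZ_COUNTS = [
    [36, 4, 0, 0],
    [3, 70, 11, 0],
    [0, 10, 48, 4],
    [0, 1, 5, 10],
]


@pytest.fixture
def torture_table():
    return from_counts(TORTURE_COUNTS, labels=["0", "1", "2", "3"])


@pytest.fixture
def no_gz_table():
    return from_counts(TORTURE_NO_GZ_COUNTS, labels=["0", "1", "2", "3"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tables(rng, count, R=3, n_low=20, n_high=200):
    """Random non-degenerate agreement tables for property tests."""
    out = []
    while len(out) < count:
        n = int(rng.integers(n_low, n_high))
        probs = rng.dirichlet(np.ones(R * R))
        counts = rng.multinomial(n, probs).reshape(R, R)
        if counts.sum() > 0:
            out.append(from_counts(counts))
    return out
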