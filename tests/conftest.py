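import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_asi(intensities):
    """Exhaustive O(n^2) ASI oracle: every cyclic half-window summed directly."""
    y = np.asarray(intensities, dtype=float)
    n = y.size
    half = n // 2
    total = y.sum()
    best = 0.0
    for start in range(n):
        idx = (start + np.arange(half)) % n
        s = y[idx].sum()
        best = max(best, abs(s - (total - s)) / total)
    return best


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (within a relative
    tolerance for floating-point ties).
    """
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)
    )
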